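"""Workflow orchestration: generate -> featurize -> simulate/import densities
-> train -> evaluate -> mine, plus a deterministic miniature fixture
generator used by the test suite and the examples.

A run directory accumulates one artifact set per stage and a ``manifest.json``
recording, per stage, the output files with SHA-256 hashes, the seed, and the
package version, so any run is reconstructible from config + seed.  Stages
whose outputs already exist are skipped unless ``force`` is set.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blocks import (BuildingBlock, Library, LibraryConfig, default_block_file,
                     enumerate_library, load_building_blocks)
from .descriptors import decorrelate, descriptor_matrix
from .evaluation import calibrate_linear, regression_report
from .mining import (block_density_stats, enrichment_segments,
                     enrichment_topfraction, heteroatom_profile)
from .oracle import OracleParams, emulate_md, generate_reference_set, true_table
from .surrogate import (HyperGrid, ModelSpec, grid_search, save_model,
                        split_dataset, train)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "make_fixture",
    "build_fixture_library",
    "FIXTURE_BLOCKS",
]

#: Miniature block set for fixtures: a methylene linker, a sulfide linker,
#: a carbocycle, an S,N-heterocycle pair and a pure N-heterocycle, so
#: density-enrichment patterns have both high- and low-density drivers.
FIXTURE_BLOCKS: list[tuple[str, str, str]] = [
    ("C", "B1", "methylene linker"),
    ("S", "B2", "sulfide linker"),
    ("c1ccccc1", "B4", "benzene"),
    ("c1nncs1", "B7", "1,3,4-thiadiazole"),
    ("c1ccncc1", "B11", "pyridine"),
    ("c1cscn1", "B13", "thiazole"),
]


@dataclass
class PipelineConfig:
    """Nested stage settings; every stochastic stage derives from ``seed``."""

    seed: int = 0
    out_dir: str = "densiscreen_run"
    log_level: str = "INFO"
    library: dict = field(default_factory=dict)      # blocks_file, mw_min, mw_max, max_rings, generations
    descriptors: dict = field(default_factory=dict)  # threshold
    oracle: dict = field(default_factory=dict)       # OracleParams overrides
    densities_csv: str | None = None                 # external (id, density) table bypassing the oracle
    model: dict = field(default_factory=dict)        # grid_search, cv_folds, train_frac, spec overrides
    evaluation: dict = field(default_factory=dict)   # calibrate (bool)
    mining: dict = field(default_factory=dict)       # top_fraction, segments, elements

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def library_config(self) -> LibraryConfig:
        lib = self.library
        return LibraryConfig(mw_min=lib.get("mw_min", 150.0),
                             mw_max=lib.get("mw_max", 400.0),
                             max_rings=lib.get("max_rings", 4),
                             max_generations=lib.get("generations", 4))

    def oracle_params(self) -> OracleParams:
        kwargs = dict(self.oracle)
        kwargs.setdefault("seed", self.seed)
        return OracleParams(**kwargs)

    def model_spec(self) -> ModelSpec:
        overrides = {k: v for k, v in self.model.items()
                     if k in ModelSpec.__dataclass_fields__}
        overrides.setdefault("seed", self.seed)
        if "hidden_layers" in overrides:
            overrides["hidden_layers"] = tuple(overrides["hidden_layers"])
        return ModelSpec(**overrides)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, force: bool = False) -> Path:
    """Execute all stages; returns the run directory.

    Raises on any stage failure after writing the partial manifest, so
    completed artifacts are preserved and the failure is recorded.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    manifest: dict = {"seed": config.seed, "version": __version__, "stages": []}
    manifest_path = out / "manifest.json"

    def record(stage: str, files: list[Path], skipped: bool = False) -> None:
        manifest["stages"].append({
            "stage": stage, "skipped": skipped,
            "files": {f.name: _sha256(f) for f in files if f.exists()},
        })
        manifest_path.write_text(json.dumps(manifest, indent=2))

    try:
        # stage: library
        blocks_file = Path(config.library.get("blocks_file") or default_block_file())
        if not blocks_file.exists():
            raise FileNotFoundError(f"block file not found: {blocks_file}")
        smi_path, csv_path = out / "library.smi", out / "library.csv"
        if smi_path.exists() and csv_path.exists() and not force:
            record("library", [smi_path, csv_path], skipped=True)
            lib_df = pd.read_csv(csv_path)
        else:
            blocks = load_building_blocks(blocks_file)
            library = enumerate_library(blocks, config.library_config())
            logger.info("library: %d candidates from %d blocks",
                        len(library), len(blocks))
            library.write(out)
            lib_df = library.to_dataframe()
            record("library", [smi_path, csv_path])

        # stage: descriptors
        feat_path = out / "features.csv"
        retained_path = out / "retained_descriptors.json"
        threshold = config.descriptors.get("threshold", 0.95)
        if feat_path.exists() and retained_path.exists() and not force:
            record("descriptors", [feat_path, retained_path], skipped=True)
            features = pd.read_csv(feat_path, index_col="id")
            retained = json.loads(retained_path.read_text())["retained"]
        else:
            features = descriptor_matrix(list(lib_df["smiles"]), list(lib_df["id"]))
            mask = decorrelate(features, threshold)
            retained = [c for c in features.columns if mask[c]]
            features.to_csv(feat_path)
            retained_path.write_text(json.dumps(
                {"threshold": threshold, "retained": retained}, indent=2))
            logger.info("descriptors: %d computed, %d retained after |R|>%g filter",
                        features.shape[1], len(retained), threshold)
            record("descriptors", [feat_path, retained_path])

        # stage: densities
        dens_path = out / "densities.csv"
        params = config.oracle_params()
        if dens_path.exists() and not force:
            record("densities", [dens_path], skipped=True)
            dens_df = pd.read_csv(dens_path)
        elif config.densities_csv:
            ext = pd.read_csv(config.densities_csv)
            if not {"id", "density_kg_m3"} <= set(ext.columns):
                raise ValueError("external density table needs id, density_kg_m3")
            dens_df = ext.assign(source=ext.get("source", "external"))
            dens_df.to_csv(dens_path, index=False)
            record("densities", [dens_path])
        else:
            truth = true_table(list(lib_df["smiles"]), list(lib_df["id"]),
                               params, seed=config.seed)
            md = emulate_md(truth, params, seed=config.seed + 1)
            dens_df = pd.concat([truth, md], ignore_index=True)
            dens_df.to_csv(dens_path, index=False)
            logger.info("densities: oracle true+md for %d molecules", len(truth))
            record("densities", [dens_path])

        # stage: train + evaluate
        model_path = out / "model.joblib"
        report_path = out / "report.json"
        train_source = config.model.get("train_source", "md")
        y_df = dens_df[dens_df["source"] == train_source]
        if y_df.empty:  # external tables may carry a different tag
            y_df = dens_df[dens_df["source"] == dens_df["source"].iloc[0]]
        y = y_df.set_index("id")["density_kg_m3"].reindex(features.index)
        if y.isna().any():
            raise ValueError("density table does not cover the library")
        X = features[retained]
        if model_path.exists() and report_path.exists() and not force:
            record("model", [model_path, report_path], skipped=True)
        else:
            tr, te = split_dataset(len(y), config.model.get("train_frac", 0.8),
                                   seed=config.seed)
            spec = config.model_spec()
            if config.model.get("grid_search", False):
                spec = grid_search(X.iloc[tr], y.iloc[tr].to_numpy(),
                                   HyperGrid(), config.model.get("cv_folds", 5),
                                   seed=config.seed, base_spec=spec)
            model = train(X.iloc[tr], y.iloc[tr].to_numpy(), spec)
            save_model(model, model_path)
            report = {
                "train": regression_report(model.predict(X.iloc[tr]),
                                           y.iloc[tr].to_numpy()).to_dict(),
                "test": regression_report(model.predict(X.iloc[te]),
                                          y.iloc[te].to_numpy()).to_dict(),
                "spec": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in spec.__dict__.items()},
            }
            if config.evaluation.get("calibrate", False):
                ref = generate_reference_set(list(lib_df["smiles"]),
                                             list(lib_df["id"]), params,
                                             seed=config.seed + 2)
                ref_y = ref.set_index("id")["density_kg_m3"].reindex(features.index)
                raw = model.predict(X)
                slope, offset, corrected = calibrate_linear(raw, ref_y.to_numpy())
                report["calibration"] = {
                    "slope_fit": slope, "offset_fit": offset,
                    "post": regression_report(corrected,
                                              ref_y.to_numpy()).to_dict(),
                }
            report_path.write_text(json.dumps(report, indent=2))
            logger.info("model: test R2=%.4f MAPE=%.2f%%",
                        report["test"]["r2"], report["test"]["mape"])
            record("model", [model_path, report_path])

        # stage: mining (on the training-source densities)
        mine_files = [out / "enrichment_top.csv", out / "enrichment_segments.csv",
                      out / "block_stats.csv"]
        if all(f.exists() for f in mine_files) and not force:
            record("mining", mine_files, skipped=True)
        else:
            blocks = load_building_blocks(blocks_file)
            block_ids = [b.id for b in blocks]
            candidates = []
            from .blocks import CandidateMolecule
            for _, row in lib_df.iterrows():
                counts = {b: int(row[b]) for b in block_ids if b in row and row[b]}
                candidates.append(CandidateMolecule(row["smiles"], counts,
                                                    int(row["generation"]),
                                                    float(row["mw"]),
                                                    int(row["n_rings"])))
            library = Library(candidates, config.library_config(), blocks)
            dens = y_df[["id", "density_kg_m3"]]
            top = enrichment_topfraction(library, dens,
                                         config.mining.get("top_fraction", 0.10))
            pd.DataFrame([r.__dict__ for r in top]).to_csv(mine_files[0], index=False)
            seg = enrichment_segments(library, dens,
                                      config.mining.get("segments", 10))
            seg.z_matrix.assign(mean_density=seg.mean_density).to_csv(mine_files[1])
            stats = block_density_stats(library, dens)
            pd.DataFrame([s.__dict__ for s in stats]).to_csv(mine_files[2],
                                                             index=False)
            for elem in config.mining.get("elements", ["S", "N"]):
                prof = heteroatom_profile(library, dens, elem)
                pd.DataFrame({"bin_lo": prof.bin_edges[:-1],
                              "bin_hi": prof.bin_edges[1:],
                              "count": prof.counts,
                              "mean_density": prof.mean_density}).to_csv(
                    out / f"profile_{elem}.csv", index=False)
            record("mining", mine_files)
    except Exception as exc:
        manifest["failure"] = repr(exc)
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise
    return out


def fixture_blocks() -> list[BuildingBlock]:
    from .blocks import canonical_smiles, mol_from_smiles
    blocks = []
    for smi, bid, name in FIXTURE_BLOCKS:
        mol = mol_from_smiles(smi)
        n_handles = sum(a.GetTotalNumHs(includeNeighbors=True)
                        for a in mol.GetAtoms() if a.GetAtomicNum() != 1)
        blocks.append(BuildingBlock(bid, canonical_smiles(mol), name, n_handles))
    return blocks


def build_fixture_library(n_molecules: int = 200, seed: int = 0,
                          max_rings: int = 4, mw_max: float = 400.0) -> Library:
    """Deterministic miniature library: enumerate the fixture blocks with the
    growth cap but no weight floor, adding generations until at least
    ``n_molecules`` exist, then draw exactly ``n_molecules`` at random
    (seeded) from the candidates sorted by canonical SMILES."""
    if n_molecules > 30_000:
        raise ValueError("fixture library supports at most 30000 molecules")
    blocks = fixture_blocks()
    library = None
    for gens in (2, 3, 4):
        config = LibraryConfig(mw_min=0.0, mw_max=mw_max, max_rings=max_rings,
                               max_generations=gens)
        library = enumerate_library(blocks, config)
        if len(library) >= n_molecules:
            break
    if library is None or len(library) < n_molecules:
        raise ValueError(f"fixture enumeration yields only "
                         f"{0 if library is None else len(library)} molecules")
    ordered = sorted(library.candidates, key=lambda c: c.smiles_canonical)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(ordered), size=n_molecules, replace=False))
    return Library([ordered[i] for i in idx], library.config, library.blocks)


def make_fixture(seed: int = 0, n_molecules: int = 200,
                 out_dir: str | Path | None = None
                 ) -> tuple[Library, pd.DataFrame]:
    """Miniature data set: a ``n_molecules``-member library over the fixture
    blocks plus an oracle density table (true + md sources).  Deterministic
    given ``seed``; optionally written to ``out_dir``."""
    library = build_fixture_library(n_molecules, seed)
    params = OracleParams(seed=seed)
    smiles = [c.smiles_canonical for c in library.candidates]
    ids = library.molecule_ids()
    truth = true_table(smiles, ids, params, seed=seed)
    md = emulate_md(truth, params, seed=seed + 1)
    densities = pd.concat([truth, md], ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "blocks.smi", "w") as fh:
            for smi, bid, name in FIXTURE_BLOCKS:
                fh.write(f"{smi} {bid} {name}\n")
        library.write(out)
        densities.to_csv(out / "densities.csv", index=False)
    return library, densities
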