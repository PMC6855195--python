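"""Constrained combinatorial candidate-library enumeration.

Candidate molecules are grown by generational linking of small building
blocks: every hydrogen atom of a block is a potential attachment handle, and
a linking step deletes one hydrogen on each partner and joins the two
heavy-atom neighbours with a single bond.  A generation-``g`` molecule
therefore contains exactly ``g`` building blocks.  Growth is pruned by a
molecular-weight ceiling and a ring-count cap; the molecular-weight floor is
enforced only on finally emitted candidates so that small intermediates
(e.g. a bare methylene linker) can keep growing.

Deduplication across the whole enumeration uses canonical SMILES as the key;
the first-encountered generation and block composition are kept as
provenance when the same structure arises via different routes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors as _Desc

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "BuildingBlock",
    "LibraryConfig",
    "CandidateMolecule",
    "Library",
    "load_building_blocks",
    "default_block_file",
    "link_pair",
    "passes_constraints",
    "enumerate_library",
    "canonical_smiles",
    "hydrogen_site_classes",
]


def canonical_smiles(mol: Chem.Mol) -> str:
    """Canonical SMILES of ``mol`` with hydrogens made implicit."""
    return Chem.MolToSmiles(Chem.RemoveHs(mol))


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def _ring_count(mol: Chem.Mol) -> int:
    # smallest set of smallest rings
    return mol.GetRingInfo().NumRings()


@dataclass(frozen=True)
class BuildingBlock:
    """A molecular fragment whose hydrogen atoms are attachment handles."""

    id: str
    smiles: str
    name: str = ""
    n_handles: int = 0

    def mol(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles)


@dataclass
class LibraryConfig:
    """Growth and emission constraints for library enumeration.

    ``mw_min`` applies only to finally emitted candidates; ``mw_max`` and
    ``max_rings`` also prune growth intermediates.
    """

    mw_min: float = 150.0
    mw_max: float = 400.0
    max_rings: int = 4
    max_generations: int = 4

    def __post_init__(self) -> None:
        if not (0 <= self.mw_min < self.mw_max):
            raise ValueError("require 0 <= mw_min < mw_max")
        if self.max_rings < 0:
            raise ValueError("max_rings must be >= 0")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")

    @classmethod
    def unconstrained(cls, max_generations: int = 4) -> "LibraryConfig":
        """A config with the weight window and ring cap effectively disabled."""
        return cls(mw_min=0.0, mw_max=math.inf, max_rings=10**6,
                   max_generations=max_generations)


@dataclass
class CandidateMolecule:
    """One enumerated library member."""

    smiles_canonical: str
    block_counts: dict[str, int]
    generation: int
    mw: float
    n_rings: int

    @property
    def n_blocks(self) -> int:
        return sum(self.block_counts.values())


@dataclass
class Library:
    """Deduplicated candidate collection plus the config and blocks that built it."""

    candidates: list[CandidateMolecule]
    config: LibraryConfig
    blocks: list[BuildingBlock]

    def __len__(self) -> int:
        return len(self.candidates)

    def smiles_set(self) -> set[str]:
        return {c.smiles_canonical for c in self.candidates}

    def block_ids(self) -> list[str]:
        return [b.id for b in self.blocks]

    def to_dataframe(self) -> pd.DataFrame:
        ids = self.block_ids()
        rows = []
        for i, c in enumerate(self.candidates):
            row = {
                "id": f"M{i:06d}",
                "smiles": c.smiles_canonical,
                "generation": c.generation,
                "mw": c.mw,
                "n_rings": c.n_rings,
            }
            for b in ids:
                row[b] = c.block_counts.get(b, 0)
            rows.append(row)
        return pd.DataFrame(rows)

    def molecule_ids(self) -> list[str]:
        return [f"M{i:06d}" for i in range(len(self.candidates))]

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        """Write ``library.smi`` (SMILES<TAB>id) and ``library.csv`` sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        smi_path = out / "library.smi"
        csv_path = out / "library.csv"
        df = self.to_dataframe()
        with open(smi_path, "w") as fh:
            for _, row in df.iterrows():
                fh.write(f"{row['smiles']}\t{row['id']}\n")
        df.to_csv(csv_path, index=False)
        return smi_path, csv_path


def default_block_file() -> Path:
    """Path to the shipped 15-block set (several blocks are generic placeholders)."""
    return Path(__file__).parent / "data" / "building_blocks.smi"


def load_building_blocks(path: str | Path) -> list[BuildingBlock]:
    """Parse a block file: one ``<smiles> <id> [<name>]`` per line, ``#`` comments.

    Raises ``ValueError`` for unparseable SMILES (naming the line), duplicate
    ids, blocks without hydrogens (no linker handle), or an empty file.
    """
    path = Path(path)
    blocks: list[BuildingBlock] = []
    seen_ids: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split(None, 2)
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected '<smiles> <id> [<name>]'")
        smiles, block_id = parts[0], parts[1]
        name = parts[2].strip() if len(parts) == 3 else ""
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"line {lineno}: unparseable SMILES {smiles!r}")
        if len(Chem.GetMolFrags(mol)) != 1:
            raise ValueError(f"line {lineno}: block {block_id!r} is not connected")
        if block_id in seen_ids:
            raise ValueError(f"line {lineno}: duplicate block id {block_id!r}")
        n_handles = sum(a.GetTotalNumHs(includeNeighbors=True)
                        for a in mol.GetAtoms() if a.GetAtomicNum() != 1)
        if n_handles < 1:
            raise ValueError(
                f"line {lineno}: block {block_id!r} has no hydrogens (no linker handle)")
        seen_ids.add(block_id)
        blocks.append(BuildingBlock(id=block_id, smiles=canonical_smiles(mol),
                                    name=name, n_handles=n_handles))
    if not blocks:
        raise ValueError("no building blocks")
    return blocks


def _link_explicit(a_h: Chem.Mol, b_h: Chem.Mol, site_a: int, site_b: int) -> Chem.Mol:
    """Link two explicit-hydrogen molecules at the given hydrogen indices."""
    for mol, site, label in ((a_h, site_a, "a"), (b_h, site_b, "b")):
        if not (0 <= site < mol.GetNumAtoms()):
            raise ValueError(f"site_{label}={site} out of range")
        atom = mol.GetAtomWithIdx(site)
        if atom.GetAtomicNum() != 1:
            raise ValueError(f"site_{label}={site} is not a hydrogen atom")
        if not any(n.GetAtomicNum() != 1 for n in atom.GetNeighbors()):
            raise ValueError(f"site_{label}={site} hydrogen has no heavy neighbour")
    combo = Chem.RWMol(Chem.CombineMols(a_h, b_h))
    ia, ib = site_a, site_b + a_h.GetNumAtoms()
    na = next(n.GetIdx() for n in combo.GetAtomWithIdx(ia).GetNeighbors()
              if n.GetAtomicNum() != 1)
    nb = next(n.GetIdx() for n in combo.GetAtomWithIdx(ib).GetNeighbors()
              if n.GetAtomicNum() != 1)
    combo.GetAtomWithIdx(na).SetBoolProp("_link_a", True)
    combo.GetAtomWithIdx(nb).SetBoolProp("_link_b", True)
    for idx in sorted((ia, ib), reverse=True):
        combo.RemoveAtom(idx)
    na2 = nb2 = -1
    for atom in combo.GetAtoms():
        if atom.HasProp("_link_a"):
            na2 = atom.GetIdx()
            atom.ClearProp("_link_a")
        if atom.HasProp("_link_b"):
            nb2 = atom.GetIdx()
            atom.ClearProp("_link_b")
    combo.AddBond(na2, nb2, Chem.BondType.SINGLE)
    product = combo.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:  # valence violation etc.
        raise ValueError(f"linking produced an invalid molecule: {exc}") from exc
    return mol_from_smiles(canonical_smiles(product))


def link_pair(a: Chem.Mol, b: Chem.Mol, site_a: int, site_b: int) -> Chem.Mol:
    """Join two molecules by deleting one hydrogen on each and bonding the
    heavy-atom neighbours with a single bond.

    Site indices refer to atoms of ``Chem.AddHs(a)`` / ``Chem.AddHs(b)``
    (heavy atoms keep their indices; hydrogens are appended).  Returns the
    canonicalized, implicit-hydrogen product.
    """
    return _link_explicit(Chem.AddHs(a), Chem.AddHs(b), site_a, site_b)


def passes_constraints(mol: Chem.Mol, config: LibraryConfig, final: bool) -> bool:
    """Growth gate (``final=False``): MW ceiling and ring cap only.
    Emission gate (``final=True``): additionally the MW floor."""
    mw = _Desc.MolWt(mol)
    if mw > config.mw_max or _ring_count(mol) > config.max_rings:
        return False
    if final and mw < config.mw_min:
        return False
    return True


def hydrogen_site_classes(mol_h: Chem.Mol) -> list[int]:
    """One representative hydrogen index per symmetry-equivalence class.

    Classes are the canonical atom ranks computed without tie-breaking, so
    linking at one representative per class visits every symmetry-distinct
    product exactly once.
    """
    ranks = list(Chem.CanonicalRankAtoms(mol_h, breakTies=False))
    reps: dict[int, int] = {}
    for atom in mol_h.GetAtoms():
        if atom.GetAtomicNum() != 1:
            continue
        if not any(n.GetAtomicNum() != 1 for n in atom.GetNeighbors()):
            continue
        reps.setdefault(ranks[atom.GetIdx()], atom.GetIdx())
    return sorted(reps.values())


def enumerate_library(blocks: Sequence[BuildingBlock],
                      config: LibraryConfig) -> Library:
    """Enumerate the constrained combinatorial library.

    Generation 1 is the block set itself; generation ``g`` links every
    generation-``g-1`` member to one additional block over all
    symmetry-distinct hydrogen-site pairs.  Products failing the growth
    constraints are pruned; the final library is the deduplicated union of
    all generations, filtered with the emission gate.  Enumeration order is
    deterministic given the input block order.
    """
    if not blocks:
        raise ValueError("empty block list")
    seen: dict[str, CandidateMolecule] = {}
    current: list[CandidateMolecule] = []
    for blk in blocks:
        mol = blk.mol()
        smi = canonical_smiles(mol)
        if smi in seen:
            continue
        if not passes_constraints(mol, config, final=False):
            continue
        cand = CandidateMolecule(smi, {blk.id: 1}, 1, _Desc.MolWt(mol),
                                 _ring_count(mol))
        seen[smi] = cand
        current.append(cand)

    block_sites = []
    for blk in blocks:
        b_h = Chem.AddHs(blk.mol())
        block_sites.append((blk, b_h, hydrogen_site_classes(b_h)))

    for gen in range(2, config.max_generations + 1):
        nxt: list[CandidateMolecule] = []
        for cand in current:
            a_h = Chem.AddHs(mol_from_smiles(cand.smiles_canonical))
            sites_a = hydrogen_site_classes(a_h)
            for blk, b_h, sites_b in block_sites:
                for sa in sites_a:
                    for sb in sites_b:
                        try:
                            product = _link_explicit(a_h, b_h, sa, sb)
                        except ValueError:
                            continue
                        if not passes_constraints(product, config, final=False):
                            continue
                        smi = canonical_smiles(product)
                        if smi in seen:
                            continue
                        counts = dict(cand.block_counts)
                        counts[blk.id] = counts.get(blk.id, 0) + 1
                        new = CandidateMolecule(smi, counts, gen,
                                                _Desc.MolWt(product),
                                                _ring_count(product))
                        seen[smi] = new
                        nxt.append(new)
        current = nxt

    final = [c for c in seen.values()
             if passes_constraints(mol_from_smiles(c.smiles_canonical),
                                   config, final=True)]
    return Library(candidates=final, config=config, blocks=list(blocks))
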