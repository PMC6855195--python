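"""Synthetic packing-density oracle.

Stands in for an expensive physics-based density calculation so the whole
screening workflow (training, calibration, mining) is exercisable at desk
scale.  Three sources are emulated:

``true``
    A noise-free group-additive model: overlap-corrected additive van der
    Waals volumes give a molecular volume, and density is
    ``k_pack * MW / V_molar`` — i.e. a packing coefficient times the
    crystallographic-style mass/volume ratio.  Optional Gaussian noise when
    tabulated.
``md``
    A simulation-like source with a linear bias against the true values
    (``md = md_slope * true + md_offset + noise``).  With the default slope
    0.84 and offset 121 kg m^-3 the underestimation grows with density,
    the known failure mode of general-purpose force fields for dense
    compounds.
``experimental``
    True values plus independent Gaussian noise; exercises the linear
    calibration workflow.

All stochastic outputs are reproducible given (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _Desc

__all__ = [
    "DEFAULT_ATOMIC_VOLUMES",
    "OracleParams",
    "vdw_volume",
    "true_density",
    "true_table",
    "emulate_md",
    "generate_reference_set",
]

#: Additive atomic van der Waals volume contributions, A^3.
DEFAULT_ATOMIC_VOLUMES: dict[str, float] = {
    "H": 7.24, "C": 20.58, "N": 15.60, "O": 14.71, "S": 24.43,
}

#: A^3 per molecule -> cm^3 per mole (Avogadro * 1e-24).
_A3_TO_CM3_MOL = 0.602214076


@dataclass
class OracleParams:
    """Parameters of the synthetic density model and its biased emulations."""

    atomic_volumes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATOMIC_VOLUMES))
    bond_correction: float = 5.92          # A^3 subtracted per bond
    aromatic_ring_correction: float = 14.7  # A^3 subtracted per aromatic ring
    aliphatic_ring_correction: float = 3.8  # A^3 subtracted per non-aromatic ring
    k_pack: float = 0.60                   # packing coefficient, (0, 1]
    noise_sd_true: float = 20.0            # kg m^-3
    md_slope: float = 0.84
    md_offset: float = 121.0               # kg m^-3
    noise_sd_md: float = 15.0              # kg m^-3
    noise_sd_exp: float = 20.0             # kg m^-3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.atomic_volumes.values()):
            raise ValueError("atomic volumes must be positive")
        if not (0 < self.k_pack <= 1):
            raise ValueError("k_pack must be in (0, 1]")
        for sd in (self.noise_sd_true, self.noise_sd_md, self.noise_sd_exp):
            if sd < 0:
                raise ValueError("noise sds must be >= 0")


def vdw_volume(mol: Chem.Mol, params: OracleParams | None = None) -> float:
    """Overlap-corrected additive van der Waals volume, A^3.

    Sum of atomic contributions minus a correction per bond and per
    (aromatic / aliphatic) ring, all evaluated on the explicit-hydrogen
    structure.
    """
    if params is None:
        params = OracleParams()
    mol_h = Chem.AddHs(mol)
    total = 0.0
    for atom in mol_h.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in params.atomic_volumes:
            raise ValueError(f"element {sym!r} missing from atomic_volumes")
        total += params.atomic_volumes[sym]
    total -= params.bond_correction * mol_h.GetNumBonds()
    n_aromatic = 0
    n_aliphatic = 0
    for ring in mol_h.GetRingInfo().BondRings():
        if all(mol_h.GetBondWithIdx(b).GetIsAromatic() for b in ring):
            n_aromatic += 1
        else:
            n_aliphatic += 1
    total -= params.aromatic_ring_correction * n_aromatic
    total -= params.aliphatic_ring_correction * n_aliphatic
    if total <= 0:
        raise ValueError("non-positive van der Waals volume")
    return total


def true_density(mol: Chem.Mol, params: OracleParams | None = None) -> float:
    """Noise-free oracle density, kg m^-3: ``k_pack * MW / V_molar``."""
    if params is None:
        params = OracleParams()
    v_molar_cm3 = vdw_volume(mol, params) * _A3_TO_CM3_MOL  # cm^3/mol
    return 1000.0 * params.k_pack * _Desc.MolWt(mol) / v_molar_cm3


def _table(ids, values, source: str) -> pd.DataFrame:
    df = pd.DataFrame({"id": list(ids),
                       "density_kg_m3": np.asarray(values, dtype=float),
                       "source": source})
    if (df["density_kg_m3"] <= 0).any():
        raise ValueError("non-positive density generated")
    return df


def true_table(smiles: list[str], ids: list[str] | None = None,
               params: OracleParams | None = None,
               seed: int | None = None) -> pd.DataFrame:
    """Density table (source=``true``) for a list of SMILES, with Gaussian
    noise of sd ``noise_sd_true`` added to the noise-free model."""
    if params is None:
        params = OracleParams()
    if ids is None:
        ids = [f"M{i:06d}" for i in range(len(smiles))]
    rng = np.random.default_rng(params.seed if seed is None else seed)
    base = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        base.append(true_density(mol, params))
    values = np.asarray(base)
    if params.noise_sd_true > 0:
        values = values + rng.normal(0.0, params.noise_sd_true, size=len(values))
    return _table(ids, values, "true")


def emulate_md(true_values: pd.DataFrame, params: OracleParams | None = None,
               seed: int | None = None) -> pd.DataFrame:
    """Biased simulation-like table: ``md_slope * true + md_offset + noise``."""
    if params is None:
        params = OracleParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    true = true_values["density_kg_m3"].to_numpy(dtype=float)
    md = params.md_slope * true + params.md_offset
    if params.noise_sd_md > 0:
        md = md + rng.normal(0.0, params.noise_sd_md, size=len(md))
    return _table(true_values["id"], md, "md")


def generate_reference_set(smiles: list[str], ids: list[str] | None = None,
                           params: OracleParams | None = None,
                           seed: int | None = None) -> pd.DataFrame:
    """Experimental-like table: noise-free true density plus independent
    Gaussian noise of sd ``noise_sd_exp`` (source=``experimental``)."""
    if params is None:
        params = OracleParams()
    if not smiles:
        raise ValueError("need at least one molecule")
    if ids is None:
        ids = [f"M{i:06d}" for i in range(len(smiles))]
    rng = np.random.default_rng(params.seed if seed is None else seed)
    base = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        base.append(true_density(mol, params))
    values = np.asarray(base)
    if params.noise_sd_exp > 0:
        values = values + rng.normal(0.0, params.noise_sd_exp, size=len(values))
    return _table(ids, values, "experimental")
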