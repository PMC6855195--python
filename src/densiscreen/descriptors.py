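"""Constitutional and functional-group-count molecular descriptors, plus the
pairwise-correlation redundancy filter.

The feature set deliberately contains only two families — constitutional
indices (atom/bond/ring counts, molecular weight, heteroatom mass fractions)
and functional-group counts from a configurable SMARTS list — i.e. cheap
2-D features with no conformer dependence.  Redundant descriptors are pruned
with a greedy pairwise filter: while any retained pair correlates beyond the
threshold, the member of the worst pair that is on average more correlated
with everything else is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _Desc
from rdkit.Chem import rdMolDescriptors

__all__ = [
    "DEFAULT_PATTERNS",
    "compute_descriptors",
    "element_weight_percent",
    "descriptor_matrix",
    "decorrelate",
    "DescriptorMatrix",
]

#: Named SMARTS patterns counted as functional-group descriptors.  Users can
#: pass their own mapping to :func:`compute_descriptors` to extend the set.
DEFAULT_PATTERNS: dict[str, str] = {
    "fg_ether": "[OD2]([#6])[#6]",
    "fg_thioether": "[SD2]([#6])[#6]",
    "fg_hydroxyl": "[OX2H]",
    "fg_amine": "[NX3;!$([NX3]=*);!a]",
    "fg_aromatic_N": "[n]",
    "fg_aromatic_NH": "[nH]",
    "fg_aromatic_S": "[s]",
    "fg_aromatic_O": "[o]",
    "fg_carbonyl": "[CX3]=[OX1]",
    "fg_nitrile": "[CX2]#[NX1]",
    "fg_S_heterocycle5": "[s;r5]",
    "fg_N_heterocycle5": "[n;r5]",
    "fg_methyl": "[CX4H3]",
}

_COMPILED: dict[str, Chem.Mol] = {}


def _pattern(smarts: str) -> Chem.Mol:
    patt = _COMPILED.get(smarts)
    if patt is None:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS pattern: {smarts!r}")
        _COMPILED[smarts] = patt
    return patt


def element_weight_percent(mol: Chem.Mol, element: str) -> float:
    """Mass fraction (0..1) of ``element`` in the molecule, hydrogens included."""
    pt = Chem.GetPeriodicTable()
    try:
        aw = pt.GetAtomicWeight(element)
    except Exception as exc:
        raise ValueError(f"unknown element symbol {element!r}") from exc
    if aw <= 0:
        raise ValueError(f"unknown element symbol {element!r}")
    mass = 0.0
    n_h = 0
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == element:
            mass += aw
        if atom.GetAtomicNum() != 1:
            n_h += atom.GetTotalNumHs(includeNeighbors=True)
    if element == "H":
        mass = n_h * aw
    return mass / _Desc.MolWt(mol)


def compute_descriptors(mol: Chem.Mol,
                        patterns: dict[str, str] | None = None) -> dict[str, float]:
    """Descriptor vector of a molecule as an ordered name->value mapping.

    Constitutional part: element counts (C,H,N,O,S), heavy-atom count, bond
    counts (total heavy-heavy, aromatic, rotatable), ring counts (total,
    aromatic), molecular weight, and N/O/S mass fractions.  Functional-group
    part: substructure-match counts of ``patterns`` (default
    :data:`DEFAULT_PATTERNS`).
    """
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError("molecule has no atoms")
    if patterns is None:
        patterns = DEFAULT_PATTERNS
    counts = {"C": 0, "N": 0, "O": 0, "S": 0}
    n_h = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym in counts:
            counts[sym] += 1
        if atom.GetAtomicNum() == 1:
            n_h += 1
        else:
            n_h += atom.GetTotalNumHs()
    ring_info = mol.GetRingInfo()
    n_aromatic_rings = rdMolDescriptors.CalcNumAromaticRings(mol)
    vec: dict[str, float] = {
        "n_C": counts["C"],
        "n_H": n_h,
        "n_N": counts["N"],
        "n_O": counts["O"],
        "n_S": counts["S"],
        "n_heavy": mol.GetNumHeavyAtoms(),
        "n_bonds": mol.GetNumBonds(),
        "n_aromatic_bonds": sum(b.GetIsAromatic() for b in mol.GetBonds()),
        "n_rotatable": rdMolDescriptors.CalcNumRotatableBonds(mol),
        "n_rings": ring_info.NumRings(),
        "n_aromatic_rings": n_aromatic_rings,
        "mw": _Desc.MolWt(mol),
        "wfrac_N": element_weight_percent(mol, "N"),
        "wfrac_O": element_weight_percent(mol, "O"),
        "wfrac_S": element_weight_percent(mol, "S"),
    }
    for name, smarts in patterns.items():
        vec[name] = float(len(mol.GetSubstructMatches(_pattern(smarts),
                                                      uniquify=True)))
    if not all(np.isfinite(v) for v in vec.values()):
        raise ValueError("non-finite descriptor value")
    return vec


def descriptor_matrix(smiles: list[str], ids: list[str] | None = None,
                      patterns: dict[str, str] | None = None) -> pd.DataFrame:
    """Descriptor matrix for a list of SMILES (rows indexed by molecule id)."""
    if ids is None:
        ids = [f"M{i:06d}" for i in range(len(smiles))]
    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        rows.append(compute_descriptors(mol, patterns))
    return pd.DataFrame(rows, index=pd.Index(ids, name="id"))


def decorrelate(matrix: pd.DataFrame, threshold: float = 0.95) -> pd.Series:
    """Boolean retained-mask over descriptor columns after redundancy filtering.

    Constant columns (undefined correlation) are dropped first.  Then,
    while any retained pair has \\|Pearson R\\| > ``threshold``: take the
    most-correlated pair and drop the member whose mean \\|R\\| against all
    other retained descriptors is larger; ties drop the higher column index.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to compute correlations")
    values = matrix.to_numpy(dtype=float)
    n_cols = values.shape[1]
    stds = values.std(axis=0)
    retained = [j for j in range(n_cols) if stds[j] > 0]
    if len(retained) >= 2:
        corr = np.abs(np.corrcoef(values[:, retained], rowvar=False))
        np.fill_diagonal(corr, 0.0)
        # local index into `retained`
        alive = list(range(len(retained)))
        while len(alive) >= 2:
            sub = corr[np.ix_(alive, alive)]
            best = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[best] <= threshold:
                break
            i, j = sorted((alive[best[0]], alive[best[1]]))
            others_i = [a for a in alive if a != i]
            others_j = [a for a in alive if a != j]
            mean_i = corr[i, others_i].mean()
            mean_j = corr[j, others_j].mean()
            drop = i if mean_i > mean_j else j  # tie -> higher index j
            alive.remove(drop)
        kept_global = {retained[a] for a in alive}
    elif len(retained) == 1:
        kept_global = {retained[0]}
    else:
        kept_global = set()
    mask = pd.Series([j in kept_global for j in range(n_cols)],
                     index=matrix.columns, name="retained")
    return mask


@dataclass
class DescriptorMatrix:
    """Descriptor matrix with its post-decorrelation retained mask."""

    data: pd.DataFrame
    threshold: float = 0.95
    retained_mask: pd.Series | None = None

    def decorrelate(self, threshold: float | None = None) -> pd.Series:
        if threshold is not None:
            self.threshold = threshold
        self.retained_mask = decorrelate(self.data, self.threshold)
        return self.retained_mask

    def retained(self) -> pd.DataFrame:
        if self.retained_mask is None:
            self.decorrelate()
        return self.data.loc[:, self.retained_mask]

    @classmethod
    def from_smiles(cls, smiles: list[str], ids: list[str] | None = None,
                    threshold: float = 0.95,
                    patterns: dict[str, str] | None = None) -> "DescriptorMatrix":
        return cls(data=descriptor_matrix(smiles, ids, patterns),
                   threshold=threshold)
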