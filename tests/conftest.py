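"""Shared fixtures and independent reference implementations.

The reference implementations here (brute-force enumerator, naive metric
suite) are deliberately written from scratch — naive loops, no shared code
with the package — so they can serve as oracles for equivalence tests.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from rdkit import Chem, RDLogger

from densiscreen import BuildingBlock

RDLogger.DisableLog("rdApp.*")


# ---------------------------------------------------------------- oracles

def bruteforce_link(smiles_a: str, smiles_b: str, h_a: int, h_b: int) -> str | None:
    """Naive H-H linking: independent of densiscreen.blocks internals."""
    a = Chem.AddHs(Chem.MolFromSmiles(smiles_a))
    b = Chem.AddHs(Chem.MolFromSmiles(smiles_b))
    combo = Chem.RWMol(Chem.CombineMols(a, b))
    ia, ib = h_a, h_b + a.GetNumAtoms()
    atom_a, atom_b = combo.GetAtomWithIdx(ia), combo.GetAtomWithIdx(ib)
    if atom_a.GetAtomicNum() != 1 or atom_b.GetAtomicNum() != 1:
        return None
    heavy_a = [n.GetIdx() for n in atom_a.GetNeighbors() if n.GetAtomicNum() != 1]
    heavy_b = [n.GetIdx() for n in atom_b.GetNeighbors() if n.GetAtomicNum() != 1]
    if not heavy_a or not heavy_b:
        return None
    na, nb = heavy_a[0], heavy_b[0]
    # removal shifts indices above the removed atom down by one
    for idx in sorted((ia, ib), reverse=True):
        combo.RemoveAtom(idx)
        na -= na > idx
        nb -= nb > idx
    combo.AddBond(na, nb, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(Chem.RemoveHs(mol))


def bruteforce_enumerate(block_smiles: list[str], generations: int) -> set[str]:
    """Independent enumerator: nested loops over ALL hydrogen pairs (no
    symmetry reduction), previous-generation x block linking, set dedup."""
    canon = [Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in block_smiles]
    seen: set[str] = set(canon)
    current = list(dict.fromkeys(canon))
    for _ in range(generations - 1):
        nxt = []
        for smi in current:
            mol_h = Chem.AddHs(Chem.MolFromSmiles(smi))
            h_sites = [a.GetIdx() for a in mol_h.GetAtoms() if a.GetAtomicNum() == 1]
            for blk in canon:
                blk_h = Chem.AddHs(Chem.MolFromSmiles(blk))
                blk_sites = [a.GetIdx() for a in blk_h.GetAtoms()
                             if a.GetAtomicNum() == 1]
                for sa in h_sites:
                    for sb in blk_sites:
                        product = bruteforce_link(smi, blk, sa, sb)
                        if product is not None and product not in seen:
                            seen.add(product)
                            nxt.append(product)
        current = nxt
    return seen


def naive_metrics(pred, ref) -> dict[str, float]:
    """Pure-python metric suite used as an equivalence oracle."""
    n = len(pred)
    e = [pred[i] - ref[i] for i in range(n)]
    pe = [100.0 * e[i] / ref[i] for i in range(n)]
    mean = lambda xs: math.fsum(xs) / len(xs)
    mp, mr = mean(list(pred)), mean(list(ref))
    cov = math.fsum((pred[i] - mp) * (ref[i] - mr) for i in range(n)) / (n - 1)
    vp = math.fsum((p - mp) ** 2 for p in pred) / (n - 1)
    vr = math.fsum((r - mr) ** 2 for r in ref) / (n - 1)
    rho = cov / math.sqrt(vp * vr)
    slope = cov / vp
    return {
        "r2": rho * rho,
        "slope": slope,
        "offset": mr - slope * mp,
        "mae": mean([abs(x) for x in e]),
        "mape": mean([abs(x) for x in pe]),
        "rmse": math.sqrt(mean([x * x for x in e])),
        "rmspe": math.sqrt(mean([x * x for x in pe])),
        "me": mean(e),
        "mpe": mean(pe),
        "maxae": max(abs(x) for x in e),
        "maxape": max(abs(x) for x in pe),
    }


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def benzene():
    return Chem.MolFromSmiles("c1ccccc1")


@pytest.fixture(scope="session")
def methane():
    return Chem.MolFromSmiles("C")


@pytest.fixture(scope="session")
def thiophene():
    return Chem.MolFromSmiles("c1ccsc1")


@pytest.fixture(scope="session")
def small_blocks():
    return [
        BuildingBlock("Me", "C", "methane", 4),
        BuildingBlock("Bz", "c1ccccc1", "benzene", 6),
        BuildingBlock("Th", "c1ccsc1", "thiophene", 4),
    ]


@pytest.fixture(scope="session")
def fixture_library_200():
    from densiscreen import make_fixture
    return make_fixture(seed=11, n_molecules=200)
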