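"""Structure-property pattern mining.

Hypergeometric Z-score enrichment of building blocks in density-selected
subsets, per-block density statistics, and heteroatom weight-percent
profiles.  The hypergeometric model draws molecules (not block instances):
``K`` and ``k`` count molecules *containing* a block at least once, in the
full library and in the subset respectively, and

    z = (k - m K / M) / sqrt(m (K/M) (1 - K/M) (M - m) / (M - 1))

is the standardized deviation from sampling without replacement.  Degenerate
cases (a block in every molecule or in none, or a trivial subset) have zero
variance and return z = 0 with an explicit flag so full block-by-segment
matrices are always emitted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .blocks import Library
from .descriptors import element_weight_percent

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "BlockDensityStat",
    "HeteroatomProfile",
    "SegmentEnrichment",
    "zscore_hypergeometric",
    "enrichment_topfraction",
    "enrichment_segments",
    "block_density_stats",
    "heteroatom_profile",
]


@dataclass
class EnrichmentResult:
    """Z-score of one block in one subset, with the underlying counts."""

    block_id: str
    subset_label: str
    M: int
    m: int
    K: int
    k: int
    z: float
    sigma_zero: bool = False


@dataclass
class BlockDensityStat:
    """Mean and population sd of density over molecules containing a block."""

    block_id: str
    n_molecules: int
    mean_density: float
    sd_density: float


@dataclass
class HeteroatomProfile:
    """Per-bin mean density over weight-percent bins of one element."""

    element: str
    bin_edges: np.ndarray
    counts: np.ndarray
    mean_density: np.ndarray  # NaN for empty bins


@dataclass
class SegmentEnrichment:
    """Block-by-segment Z-score matrix over a density-sorted library."""

    z_matrix: pd.DataFrame          # rows: segment 1..n, cols: block ids
    results: list[list[EnrichmentResult]]
    mean_density: pd.Series         # per-segment mean density


def zscore_hypergeometric(M: int, m: int, K: int, k: int) -> float:
    """Standardized block count under the hypergeometric null.

    ``M``: library size, ``m``: subset size, ``K``: molecules containing the
    block in the library, ``k``: in the subset.  Zero-variance cases return
    0.0 (use :func:`_zscore_full` for the flag).
    """
    z, _ = _zscore_full(M, m, K, k)
    return z


def _zscore_full(M: int, m: int, K: int, k: int) -> tuple[float, bool]:
    if M <= 0:
        raise ValueError("M must be positive")
    if not (0 <= m <= M and 0 <= K <= M):
        raise ValueError("require 0 <= m, K <= M")
    if not (0 <= k <= min(m, K)):
        raise ValueError(f"infeasible count k={k} for m={m}, K={K}")
    if m - k > M - K:
        raise ValueError("infeasible count: subset has too few block-free molecules")
    if M == 1 or K in (0, M) or m in (0, M):
        logger.warning("zero-variance hypergeometric case (M=%d, m=%d, K=%d)",
                       M, m, K)
        return 0.0, True
    p = K / M
    mu = m * p
    var = m * p * (1 - p) * (M - m) / (M - 1)
    return (k - mu) / math.sqrt(var), False


def _density_map(densities) -> dict[str, float]:
    if isinstance(densities, pd.DataFrame):
        return dict(zip(densities["id"], densities["density_kg_m3"]))
    return dict(densities)


def _containment(library: Library) -> tuple[list[str], dict[str, set[int]]]:
    """Block id -> set of candidate indices containing it (binary containment)."""
    block_ids = library.block_ids()
    members: dict[str, set[int]] = {b: set() for b in block_ids}
    for i, cand in enumerate(library.candidates):
        for b, count in cand.block_counts.items():
            if count > 0 and b in members:
                members[b].add(i)
    return block_ids, members


def _ordered_indices(library: Library, dens: dict[str, float],
                     descending: bool) -> list[int]:
    ids = library.molecule_ids()
    missing = [mid for mid in ids if mid not in dens]
    if missing:
        raise ValueError(f"{len(missing)} library molecules lack a density "
                         f"(first: {missing[0]})")
    sign = -1.0 if descending else 1.0
    return sorted(range(len(ids)), key=lambda i: (sign * dens[ids[i]], ids[i]))


def enrichment_topfraction(library: Library, densities, q: float = 0.10
                           ) -> list[EnrichmentResult]:
    """Block enrichment in the ceil(q*M) highest-density molecules.

    Positive z means the block is overexpressed in the high-density subset.
    Ties at the boundary are broken by molecule id (stable, reproducible).
    """
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    dens = _density_map(densities)
    order = _ordered_indices(library, dens, descending=True)
    M = len(order)
    m = math.ceil(q * M)
    subset = set(order[:m])
    block_ids, members = _containment(library)
    label = f"top{100 * q:g}%"
    results = []
    for b in block_ids:
        K = len(members[b])
        k = len(members[b] & subset)
        z, flag = _zscore_full(M, m, K, k)
        results.append(EnrichmentResult(b, label, M, m, K, k, z, flag))
    return results


def enrichment_segments(library: Library, densities, n_segments: int = 10
                        ) -> SegmentEnrichment:
    """Block-by-segment enrichment over the density-sorted library.

    Segments are contiguous equal-size slices in ascending density order
    (any remainder spread over the leading segments), so per-segment mean
    densities are non-decreasing and each block's k sums to its K.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    dens = _density_map(densities)
    order = _ordered_indices(library, dens, descending=False)
    M = len(order)
    if M < n_segments:
        raise ValueError("library smaller than the number of segments")
    base, rem = divmod(M, n_segments)
    block_ids, members = _containment(library)
    ids = library.molecule_ids()
    results: list[list[EnrichmentResult]] = []
    mean_d = []
    z_rows = []
    start = 0
    for s in range(n_segments):
        size = base + (1 if s < rem else 0)
        seg = order[start:start + size]
        start += size
        seg_set = set(seg)
        label = f"segment {s + 1}"
        row = []
        for b in block_ids:
            K = len(members[b])
            k = len(members[b] & seg_set)
            z, flag = _zscore_full(M, size, K, k)
            row.append(EnrichmentResult(b, label, M, size, K, k, z, flag))
        results.append(row)
        z_rows.append([r.z for r in row])
        mean_d.append(float(np.mean([dens[ids[i]] for i in seg])))
    z_matrix = pd.DataFrame(z_rows, columns=block_ids,
                            index=pd.Index(range(1, n_segments + 1),
                                           name="segment"))
    return SegmentEnrichment(z_matrix=z_matrix, results=results,
                             mean_density=pd.Series(mean_d, index=z_matrix.index,
                                                    name="mean_density"))


def block_density_stats(library: Library, densities) -> list[BlockDensityStat]:
    """Mean and population sd of density per block, over the molecules that
    contain it (multiple occurrences in one molecule count once)."""
    dens = _density_map(densities)
    ids = library.molecule_ids()
    block_ids, members = _containment(library)
    stats = []
    for b in block_ids:
        idxs = sorted(members[b])
        if not idxs:
            logger.warning("block %s contained in no molecule; omitted", b)
            continue
        values = np.array([dens[ids[i]] for i in idxs])
        stats.append(BlockDensityStat(b, len(values),
                                      float(values.mean()),
                                      float(values.std(ddof=0))))
    return stats


def heteroatom_profile(library: Library, densities, element: str,
                       bin_width: float = 0.05) -> HeteroatomProfile:
    """Bin molecules by the weight fraction of ``element`` and report per-bin
    counts and mean density.  Bins cover [0, 1]; the last bin is closed."""
    if not (0 < bin_width <= 1):
        raise ValueError("bin_width must be in (0, 1]")
    dens = _density_map(densities)
    ids = library.molecule_ids()
    n_bins = math.ceil(1.0 / bin_width)
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    counts = np.zeros(n_bins, dtype=int)
    sums = np.zeros(n_bins)
    for i, cand in enumerate(library.candidates):
        mol = Chem.MolFromSmiles(cand.smiles_canonical)
        w = element_weight_percent(mol, element)
        b = min(int(w / bin_width), n_bins - 1)
        counts[b] += 1
        sums[b] += dens[ids[i]]
    with np.errstate(invalid="ignore"):
        mean_density = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return HeteroatomProfile(element=element, bin_edges=edges,
                             counts=counts, mean_density=mean_density)
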