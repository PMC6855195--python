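"""Hypergeometric enrichment, per-block statistics, heteroatom profiles."""

import math

import numpy as np
import pandas as pd
import pytest

from densiscreen import (BuildingBlock, Library, LibraryConfig,
                         block_density_stats, enrichment_segments,
                         enrichment_topfraction, heteroatom_profile,
                         zscore_hypergeometric)
from densiscreen.blocks import CandidateMolecule


def _toy_library(n=40, seed=0):
    """Hand-built library: half the molecules contain block X, half block Y;
    densities rise with molecule index."""
    blocks = [BuildingBlock("X", "c1nncs1", "", 2),
              BuildingBlock("Y", "C", "", 4),
              BuildingBlock("Z", "c1ccccc1", "", 6)]
    candidates = []
    for i in range(n):
        counts = {"X": 1} if i % 2 == 0 else {"Y": 1}
        counts["Z"] = 1  # Z in every molecule
        candidates.append(CandidateMolecule(
            "c1ccccc1" if i % 2 else "c1nncs1", counts, 2, 160.0, 1))
    return Library(candidates, LibraryConfig.unconstrained(), blocks)


def _densities(library, values):
    return pd.DataFrame({"id": library.molecule_ids(),
                         "density_kg_m3": values, "source": "true"})


class TestZscore:
    def test_expectation_gives_zero(self):
        assert zscore_hypergeometric(100, 50, 10, 5) == pytest.approx(0.0)

    def test_worked_case_closed_form(self):
        var = 50 * 0.1 * 0.9 * (50 / 99)
        expected = (10 - 5) / math.sqrt(var)
        assert zscore_hypergeometric(100, 50, 10, 10) == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(3.3166, abs=1e-4)

    def test_infeasible_counts_error(self):
        with pytest.raises(ValueError, match="infeasible"):
            zscore_hypergeometric(100, 50, 10, 11)
        with pytest.raises(ValueError, match="infeasible"):
            zscore_hypergeometric(10, 9, 2, 0)  # 9 subset, only 8 block-free

    def test_zero_variance_returns_zero(self):
        assert zscore_hypergeometric(100, 50, 100, 50) == 0.0
        assert zscore_hypergeometric(100, 0, 10, 0) == 0.0

    def test_monte_carlo_matches_closed_form_moments(self):
        M, m, K = 200, 60, 35
        rng = np.random.default_rng(7)
        draws = rng.hypergeometric(K, M - K, m, size=100_000)
        mu = m * K / M
        sd = math.sqrt(m * (K / M) * (1 - K / M) * (M - m) / (M - 1))
        assert draws.mean() == pytest.approx(mu, rel=0.01)
        assert draws.std() == pytest.approx(sd, rel=0.01)
        z = (draws - mu) / sd
        assert abs(z.mean()) < 0.02 and abs(z.std() - 1) < 0.02


class TestTopFraction:
    def test_subset_size_is_ceil(self):
        lib = _toy_library(40)
        dens = _densities(lib, np.linspace(1000, 1400, 40))
        results = enrichment_topfraction(lib, dens, q=0.10)
        assert all(r.m == 4 for r in results)
        assert all(r.M == 40 for r in results)

    def test_block_in_every_molecule_flagged_zero(self):
        lib = _toy_library(40)
        dens = _densities(lib, np.linspace(1000, 1400, 40))
        by_id = {r.block_id: r for r in enrichment_topfraction(lib, dens, 0.10)}
        assert by_id["Z"].z == 0.0 and by_id["Z"].sigma_zero

    def test_enriched_block_positive_depleted_negative(self):
        lib = _toy_library(40)
        # even indices (block X) get the highest densities
        values = [1400.0 + i if i % 2 == 0 else 1000.0 + i for i in range(40)]
        by_id = {r.block_id: r for r in enrichment_topfraction(lib, _densities(lib, values), 0.25)}
        assert by_id["X"].z > 0 > by_id["Y"].z

    def test_invalid_fraction_errors(self):
        lib = _toy_library(10)
        dens = _densities(lib, np.linspace(1000, 1100, 10))
        with pytest.raises(ValueError):
            enrichment_topfraction(lib, dens, q=1.5)

    def test_missing_density_errors(self):
        lib = _toy_library(10)
        dens = _densities(lib, np.linspace(1000, 1100, 10)).iloc[:-1]
        with pytest.raises(ValueError, match="lack a density"):
            enrichment_topfraction(lib, dens, q=0.2)


class TestSegments:
    def test_counts_conserved_and_means_nondecreasing(self):
        lib = _toy_library(43)  # remainder spread over leading segments
        rng = np.random.default_rng(1)
        dens = _densities(lib, rng.uniform(900, 1800, size=43))
        seg = enrichment_segments(lib, dens, n_segments=10)
        sizes = [row[0].m for row in seg.results]
        assert sum(sizes) == 43 and max(sizes) - min(sizes) == 1
        assert sizes == sorted(sizes, reverse=True)
        for b in ("X", "Y", "Z"):
            ks = [next(r.k for r in row if r.block_id == b)
                  for row in seg.results]
            K = next(r.K for r in seg.results[0] if r.block_id == b)
            assert sum(ks) == K
        diffs = np.diff(seg.mean_density.to_numpy())
        assert (diffs >= -1e-9).all()

    def test_permutation_invariance(self):
        lib = _toy_library(30)
        rng = np.random.default_rng(2)
        values = rng.uniform(900, 1800, size=30)
        dens = _densities(lib, values)
        shuffled = dens.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = enrichment_segments(lib, dens, 5).z_matrix
        b = enrichment_segments(lib, shuffled, 5).z_matrix
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_segments_errors(self):
        lib = _toy_library(10)
        dens = _densities(lib, np.linspace(1000, 1100, 10))
        with pytest.raises(ValueError):
            enrichment_segments(lib, dens, n_segments=1)


class TestBlockStats:
    def test_equal_densities_give_zero_sd(self):
        lib = _toy_library(20)
        stats = block_density_stats(lib, _densities(lib, [1300.0] * 20))
        assert all(s.mean_density == 1300.0 and s.sd_density == 0.0
                   for s in stats)

    def test_hand_computed_mean_and_population_sd(self):
        blocks = [BuildingBlock("X", "C", "", 4)]
        candidates = [CandidateMolecule("C", {"X": 1}, 1, 16.0, 0),
                      CandidateMolecule("CC", {"X": 2}, 2, 30.1, 0)]
        lib = Library(candidates, LibraryConfig.unconstrained(), blocks)
        stats = block_density_stats(lib, _densities(lib, [1000.0, 1200.0]))
        assert stats[0].n_molecules == 2  # two occurrences in CC count once
        assert stats[0].mean_density == pytest.approx(1100.0)
        assert stats[0].sd_density == pytest.approx(100.0)


class TestHeteroatomProfile:
    def test_hydrocarbons_fall_in_first_sulfur_bin(self):
        blocks = [BuildingBlock("Z", "c1ccccc1", "", 6)]
        candidates = [CandidateMolecule("c1ccccc1", {"Z": 1}, 1, 78.1, 1),
                      CandidateMolecule("Cc1ccccc1", {"Z": 1}, 2, 92.1, 1)]
        lib = Library(candidates, LibraryConfig.unconstrained(), blocks)
        prof = heteroatom_profile(lib, _densities(lib, [950.0, 940.0]), "S")
        assert prof.counts[0] == 2 and prof.counts[1:].sum() == 0
        assert prof.mean_density[0] == pytest.approx(945.0)

    def test_bin_counts_partition_library(self, fixture_library_200):
        library, densities = fixture_library_200
        truth = densities[densities["source"] == "true"]
        prof = heteroatom_profile(library, truth, "N")
        assert prof.counts.sum() == len(library)
        assert prof.bin_edges[0] == 0.0 and prof.bin_edges[-1] == 1.0

    def test_density_rises_with_sulfur_fraction(self, fixture_library_200):
        library, densities = fixture_library_200
        truth = densities[densities["source"] == "true"]
        prof = heteroatom_profile(library, truth, "S", bin_width=0.10)
        populated = [m for m, c in zip(prof.mean_density, prof.counts) if c >= 5]
        assert populated[-1] > populated[0]
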