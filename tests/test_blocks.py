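"""Library enumeration: block parsing, hydrogen-handle linking, constraints,
and equivalence with a brute-force enumerator."""

import itertools

import pytest
from rdkit import Chem

from densiscreen import (BuildingBlock, LibraryConfig, default_block_file,
                         enumerate_library, link_pair, load_building_blocks,
                         passes_constraints)
from densiscreen.blocks import canonical_smiles, hydrogen_site_classes

from conftest import bruteforce_enumerate


class TestLoadBuildingBlocks:
    def test_benzene_line(self, tmp_path):
        f = tmp_path / "blocks.smi"
        f.write_text("c1ccccc1 Bz benzene\n")
        blocks = load_building_blocks(f)
        assert len(blocks) == 1
        assert blocks[0].id == "Bz"
        assert blocks[0].name == "benzene"
        assert blocks[0].n_handles == 6

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        f = tmp_path / "blocks.smi"
        f.write_text("# header\n\nC Me methane # trailing\n")
        blocks = load_building_blocks(f)
        assert [b.id for b in blocks] == ["Me"]
        assert blocks[0].n_handles == 4

    def test_empty_file_errors(self, tmp_path):
        f = tmp_path / "blocks.smi"
        f.write_text("# only a comment\n")
        with pytest.raises(ValueError, match="no building blocks"):
            load_building_blocks(f)

    def test_bad_smiles_names_line(self, tmp_path):
        f = tmp_path / "blocks.smi"
        f.write_text("C Me\nnot_a_smiles(((' X2\n")
        with pytest.raises(ValueError, match="line 2"):
            load_building_blocks(f)

    def test_duplicate_id_errors(self, tmp_path):
        f = tmp_path / "blocks.smi"
        f.write_text("C B1\nO B1\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_building_blocks(f)

    def test_no_hydrogen_block_errors(self, tmp_path):
        f = tmp_path / "blocks.smi"
        f.write_text("O=C=O X1 carbon dioxide\n")
        with pytest.raises(ValueError, match="no hydrogens"):
            load_building_blocks(f)

    def test_default_file_has_fifteen_blocks_with_named_heterocycles(self):
        blocks = load_building_blocks(default_block_file())
        assert len(blocks) == 15
        names = {b.id: b.name for b in blocks}
        assert "1,3,4-thiadiazole" in names["B7"]
        assert "thiazole" in names["B13"]
        assert all(b.n_handles >= 1 for b in blocks)


class TestLinkPair:
    def test_benzene_benzene_gives_biphenyl(self, benzene):
        product = link_pair(benzene, benzene, 6, 6)
        assert Chem.MolToSmiles(product) == Chem.CanonSmiles("c1ccc(-c2ccccc2)cc1")

    def test_methane_benzene_gives_toluene(self, methane, benzene):
        product = link_pair(methane, benzene, 1, 6)
        assert Chem.MolToSmiles(product) == Chem.CanonSmiles("Cc1ccccc1")

    def test_out_of_range_site_errors(self, benzene):
        with pytest.raises(ValueError, match="out of range"):
            link_pair(benzene, benzene, 99, 6)

    def test_non_hydrogen_site_errors(self, benzene):
        with pytest.raises(ValueError, match="not a hydrogen"):
            link_pair(benzene, benzene, 0, 6)

    def test_any_h_pair_on_benzene_gives_same_biphenyl(self, benzene):
        products = {Chem.MolToSmiles(link_pair(benzene, benzene, sa, sb))
                    for sa in range(6, 12) for sb in range(6, 12)}
        assert len(products) == 1


class TestConstraints:
    def test_benzene_below_mw_floor_at_final(self, benzene):
        config = LibraryConfig()
        assert passes_constraints(benzene, config, final=True) is False
        assert passes_constraints(benzene, config, final=False) is True

    def test_biphenyl_within_window(self):
        biphenyl = Chem.MolFromSmiles("c1ccc(-c2ccccc2)cc1")
        assert passes_constraints(biphenyl, LibraryConfig(), final=True) is True

    def test_ring_cap(self):
        five_rings = Chem.MolFromSmiles("C1CC12CC23CC34CC45CC5")
        config = LibraryConfig(mw_min=0, mw_max=1e6, max_rings=4)
        assert passes_constraints(five_rings, config, final=False) is False

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LibraryConfig(mw_min=400, mw_max=150)
        with pytest.raises(ValueError):
            LibraryConfig(max_generations=0)


class TestEnumerate:
    def test_single_block_one_generation(self):
        blocks = [BuildingBlock("Bz", "c1ccccc1", "benzene", 6)]
        lib = enumerate_library(blocks, LibraryConfig.unconstrained(1))
        assert lib.smiles_set() == {"c1ccccc1"}

    def test_methane_benzene_two_generations(self):
        blocks = [BuildingBlock("Me", "C", "", 4),
                  BuildingBlock("Bz", "c1ccccc1", "", 6)]
        lib = enumerate_library(blocks, LibraryConfig.unconstrained(2))
        expected = {Chem.CanonSmiles(s)
                    for s in ["C", "c1ccccc1", "CC", "Cc1ccccc1",
                              "c1ccc(-c2ccccc2)cc1"]}
        assert lib.smiles_set() == expected
        assert len(lib) == 5

    def test_empty_block_list_errors(self):
        with pytest.raises(ValueError, match="empty"):
            enumerate_library([], LibraryConfig())

    def test_generation_counts_blocks(self, small_blocks):
        lib = enumerate_library(small_blocks, LibraryConfig.unconstrained(3))
        for cand in lib.candidates:
            assert cand.n_blocks == cand.generation

    def test_matches_bruteforce_two_blocks_three_generations(self):
        blocks = [BuildingBlock("Me", "C", "", 4),
                  BuildingBlock("Th", "c1ccsc1", "", 4)]
        lib = enumerate_library(blocks, LibraryConfig.unconstrained(3))
        expected = bruteforce_enumerate(["C", "c1ccsc1"], 3)
        assert lib.smiles_set() == expected

    def test_block_order_permutation_invariance(self, small_blocks):
        reference = None
        for perm in itertools.permutations(small_blocks):
            lib = enumerate_library(list(perm), LibraryConfig.unconstrained(2))
            if reference is None:
                reference = lib.smiles_set()
            assert lib.smiles_set() == reference

    def test_generation_monotonicity(self, small_blocks):
        sets = [enumerate_library(small_blocks,
                                  LibraryConfig.unconstrained(g)).smiles_set()
                for g in (1, 2, 3)]
        assert sets[0] <= sets[1] <= sets[2]

    def test_emitted_smiles_are_canonical_fixed_points(self, small_blocks):
        lib = enumerate_library(small_blocks, LibraryConfig.unconstrained(2))
        for smi in lib.smiles_set():
            assert Chem.CanonSmiles(smi) == smi

    def test_constraints_prune_final_library(self, small_blocks):
        config = LibraryConfig(mw_min=150, mw_max=400, max_rings=4,
                               max_generations=3)
        lib = enumerate_library(small_blocks, config)
        df = lib.to_dataframe()
        assert (df["mw"] >= 150).all() and (df["mw"] <= 400).all()
        assert (df["n_rings"] <= 4).all()
        # intermediates below the floor still grew into emitted candidates
        assert any(c.generation >= 2 for c in lib.candidates)


def test_hydrogen_site_classes_collapse_symmetry(benzene):
    mol_h = Chem.AddHs(benzene)
    assert len(hydrogen_site_classes(mol_h)) == 1  # all 6 H equivalent
    thiophene_h = Chem.AddHs(Chem.MolFromSmiles("c1ccsc1"))
    assert len(hydrogen_site_classes(thiophene_h)) == 2  # alpha vs beta
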