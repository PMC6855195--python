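"""Featurize molecules and prune redundant descriptors.

Each molecule gets constitutional indices (atom/bond/ring counts, MW,
heteroatom mass fractions) and functional-group counts; descriptor pairs
with |Pearson R| > 0.95 are then reduced to one member each.
"""

from densiscreen import decorrelate, descriptor_matrix, make_fixture

library, _ = make_fixture(seed=0, n_molecules=200)
smiles = [c.smiles_canonical for c in library.candidates]

features = descriptor_matrix(smiles, library.molecule_ids())
mask = decorrelate(features, threshold=0.95)

print(f"{features.shape[0]} molecules x {features.shape[1]} descriptors")
print(f"{int(mask.sum())} retained after the |R|>0.95 redundancy filter:")
print(" ", ", ".join(features.columns[mask]))

one = features.iloc[0]
print(f"\nexample {smiles[0]}: MW={one['mw']:.1f} Da, "
      f"S mass fraction={one['wfrac_S']:.3f}, rings={one['n_rings']:.0f}")
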