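"""Bootstrap learning curve: accuracy vs. training-set size.

For each fraction, independent repetitions draw a training set without
replacement (the remainder is the test set), train a fresh model, and
record train/test R^2.  The curve locates where additional training data
stops paying off.
"""

from densiscreen import (ModelSpec, OracleParams, decorrelate,
                         descriptor_matrix, emulate_md, learning_curve,
                         true_table)
from densiscreen.pipeline import build_fixture_library

library = build_fixture_library(n_molecules=1000, seed=0)
smiles = [c.smiles_canonical for c in library.candidates]
ids = library.molecule_ids()
features = descriptor_matrix(smiles, ids)
X = features.loc[:, decorrelate(features)].to_numpy()
truth = true_table(smiles, ids, OracleParams(seed=0), seed=0)
y = emulate_md(truth, OracleParams(), seed=1)["density_kg_m3"].to_numpy()

points = learning_curve(X, y, fractions=(0.02, 0.05, 0.2, 0.8),
                        n_reps=5, seed=0, spec=ModelSpec(seed=0))
print("fraction  n_train  test R^2 (mean+/-sd)   train R^2")
for p in points:
    print(f"{p.fraction:7.0%}  {p.n_train:7d}  {p.mean_test_r2:.3f} "
          f"+/- {p.sd_test_r2:.3f}      {p.mean_train_r2:.3f}")
print("test R^2 rises with training size and stays below train R^2.")
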