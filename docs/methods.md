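# Methods

`densiscreen` implements a surrogate-assisted screening workflow for the
amorphous packing density of small organic molecules: enumerate a
combinatorial candidate library from molecular building blocks, featurize it
with cheap 2-D descriptors, train a neural-network surrogate against a
density source, calibrate predictions linearly against a reference set, and
mine the scored library for building-block/density patterns. This note
records the models, the defaults and why, the numerical choices, and what
the synthetic density oracle does and does not establish.

## Combinatorial library enumeration

Building blocks are small molecules whose hydrogen atoms act as linker
handles. A linking step deletes one hydrogen on each partner and joins the
two heavy-atom neighbours with a single bond. Generation 1 is the block set
itself; generation *g* links every generation-(*g*−1) member to one more
block, so a generation-*g* candidate contains exactly *g* blocks. The
default constraints are a molecular weight window of 150–400 Da, at most
four rings (smallest set of smallest rings), and four generations.

Design choices:

* **Growth vs. emission constraints.** The MW ceiling and the ring cap
  prune intermediates during growth; the MW floor applies only at final
  emission, because light intermediates (a bare methylene bridge, say) must
  be allowed to keep growing.
* **Symmetry reduction.** Hydrogen sites are grouped by canonical atom rank
  (computed without tie-breaking); only one representative per equivalence
  class is linked. This visits each symmetry-distinct product once and is
  verified against a brute-force all-pairs enumerator in the tests.
* **Deduplication.** Canonical SMILES is the library-wide key. When the same
  structure arises by different routes, the first-encountered generation and
  block composition are kept as provenance; the structure set itself is
  independent of block input order.
* **Linker blocks** (CH2, S, O bridges) are represented by their saturated
  parent molecules (methane, hydrogen sulfide, water), so all blocks are
  treated uniformly.
* Several members of the shipped 15-block file are generic
  organic-materials moieties marked as placeholders in their names; the
  named heterocycles (1,3,4- and 1,2,5-thiadiazole, thiazole, cyclopentane,
  the three linkers) are exact.

## Descriptors and redundancy filtering

Two families only, both conformer-free: constitutional indices (element
counts C/H/N/O/S, heavy atoms, bond counts, rotatable bonds, ring counts,
molecular weight, N/O/S mass fractions) and functional-group counts from a
configurable SMARTS list (ethers, thioethers, amines, aromatic
heteroatoms, carbonyls, five-membered S/N-heterocycles, ...). The default
set has 28 descriptors; users can extend the SMARTS list without touching
code.

Mutually correlated descriptors are redundant. The filter drops constant
columns (undefined correlation), then greedily: while any retained pair has
|Pearson R| above the threshold (default 0.95), take the most-correlated
pair and drop the member whose mean |R| against all other retained
descriptors is larger; ties drop the higher column index. The iteration
order is not canonical — greedy worst-pair-first was chosen for determinism
— and the post-condition (no retained pair above the threshold) is tested
on randomized collinear matrices. On the default descriptor set and fixture
libraries roughly half the columns survive.

Features are standardized (zero mean, unit variance, statistics from the
training rows only) before model training; the raw count scales otherwise
stall gradient-based optimization. The target is standardized the same way
inside `train` and predictions are returned on the original scale.

## Synthetic density oracle

The oracle replaces an expensive physics-based density calculation so every
downstream stage is testable at desk scale. It is a deliberately simple
group-additive model, not a claim about real packing physics:

* molecular volume: overlap-corrected additive van der Waals volumes,
  V = Σ atoms − 5.92 Å³·bonds − 14.7 Å³·aromatic ring − 3.8 Å³·aliphatic
  ring, with atomic contributions H 7.24, C 20.58, N 15.60, O 14.71,
  S 24.43 Å³ (standard additive-scheme values; all configurable);
* density: ρ = k_pack · MW / V_molar with packing coefficient
  k_pack = 0.60, chosen so typical fixture-library members span roughly
  750–1700 kg·m⁻³, the realistic range for dense small organics;
* the *md* source applies a linear bias, md = 0.84·true + 121 kg·m⁻³ plus
  Gaussian noise (sd 15 kg·m⁻³), reproducing the known force-field failure
  mode in which underestimation grows with density;
* the *experimental* source adds independent Gaussian noise
  (sd 20 kg·m⁻³) to the true values and exists to exercise calibration.

Because density depends on sulfur/nitrogen content through both MW and
volume, the oracle reproduces the qualitative ordering that motivates the
mining stage: S-heterocycle-rich molecules sit above pure hydrocarbons and
methylene-linked chains. What passing tests on oracle data do **not** show:
that the descriptor set suffices for real MD or experimental densities,
that real data carry an exactly linear bias, or that the surrogate's error
on real libraries matches its error here — the oracle's structure–density
map is far smoother than a simulation's. Users with real density tables
bypass the oracle through the CSV input path.

## Surrogate model

A scikit-learn multi-layer perceptron with two hidden layers of 100 units.
The hyperparameter grid covers activation {identity, tanh, relu, logistic},
L2 regularization α {1e-1 … 1e-5}, solver {sgd, adam} and learning-rate
schedule {constant, invscaling, adaptive} — 120 combinations, scored by
5-fold cross-validated squared-Pearson R² on the training split (the
selection criterion is a package choice; a fixed validation split would be
equally defensible). The defaults are the winning combination
(relu / adam / adaptive / α = 1e-4). Data are split 80/20 train/test.
Convergence settings (max 600 epochs, tolerance 1e-6, 30-epoch patience)
are generous and exposed on `ModelSpec`.

## Metric suite and calibration

Errors are e = prediction − reference; percentage metrics divide by the
reference. The report carries MAE, MAPE, RMSE, RMSPE, ME, MPE, MaxAE,
MaxAPE, plus R² (squared Pearson correlation — deliberately not the
coefficient of determination, so it coexists with a non-trivial slope), and
the slope/offset of an ordinary-least-squares fit of the *reference on the
prediction*. That regression direction is the one under which a
least-squares-calibrated predictor reports exactly slope 1 / offset 0.

Calibration fits raw = a·ref + b and corrects by inversion,
corrected = (raw − b)/a. Algebraically the corrected values always have
mean error exactly zero; the reported slope equals the squared correlation
of raw and reference, so it is exactly 1 only in the noise-free limit —
which is how the recovery of an injected (0.84, 121) bias is tested.

## Learning-curve protocol

For each training fraction (default grid 0.05%–100%) and each of 50
repetitions, a training set is drawn at random *without* replacement — so
the untouched remainder is a valid test set — a fresh model is trained, and
train/test R² are recorded; repetitions are independent re-draws and the
per-fraction mean and standard deviation (ddof = 1) are reported. The 100%
point has no held-out remainder; it is evaluated on the training rows and
flagged `train_only`. Fractions yielding fewer than two training rows are
skipped with a warning.

## Enrichment mining

For a subset of m molecules out of M, a block contained in K library
molecules and k subset molecules gets

    z = (k − mK/M) / sqrt( m·(K/M)·(1−K/M)·(M−m)/(M−1) ),

the standardized deviation under the hypergeometric null of drawing
molecules without replacement. Containment is binary — a molecule with two
copies of a block counts once — because the null draws molecules, not block
instances. Zero-variance cases (block in every molecule or none, trivial
subsets) return z = 0 with an explicit flag instead of erroring, so full
block-by-segment matrices are always emitted. Subset boundaries are made
reproducible by sorting on (density, molecule id). Per-block density
statistics use the population standard deviation (ddof = 0). Heteroatom
profiles bin molecules by element weight fraction (default bin width 0.05,
last bin closed at 1.0).

## Problem sizes in tests and the acceptance script

The enumeration equivalence check uses three blocks and three generations
(≈180 structures); the end-to-end surrogate check uses a 3000-molecule
fixture library (six blocks, up to four generations, sub-sampled
deterministically by seed); the learning curve uses 2000 of those molecules
at fractions 1/5/20/80% with 10 repetitions; Monte-Carlo Z-score checks use
10⁵ draws. These sizes were chosen so every stage's statistical claim is
sharp at desk scale while the full default configuration (15 blocks, four
generations, ~10⁶ candidates) remains a production-run setting rather than
a test setting.

## Known limitations

* The oracle's additive volume model ignores conformational packing,
  polymorphism, temperature and processing effects entirely.
* Descriptor parity with any specific commercial descriptor package is not
  attempted; only the two descriptor families are matched.
* Block occurrence counting in `block_counts` records multiplicity, but all
  enrichment statistics reduce it to binary containment.
* Stereochemistry is not enumerated; canonical SMILES deduplication treats
  stereoisomers as one structure.
* Grid search retrains 120 × cv_folds models; on large feature matrices
  this is the dominant cost and is off by default in the pipeline.
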