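# Methods

## Problem

A double-insertion mutant of a protein of length L is described by four
categorical values: two insertion slots `p1 < p2` (a slot is the 1-based
index of the wild-type residue before which the new residue goes, so the
slot vocabulary has size L) and the two inserted amino acids `a1`, `a2`.
Structure-based energy evaluation of such mutants produces, per residue,
twenty named Rosetta score terms; summing each term over residues gives one
20-score vector per mutant. `indelnet` learns to predict these scores
directly from the four categorical inputs, so that the expensive structural
evaluation can be amortized across the combinatorial mutant space.

## Preprocessing

1. **Summation.** Per-residue tables are collapsed by summing every term
   over all residue rows (`np.sum` along rows). Row indexing after
   insertion is treated as opaque because only the sums are used.
2. **Constant-term drop.** `yhh_planarity` (tyrosine hydroxyl planarity
   torsion) and `dslf_fa13` (disulfide geometry) are internally constant for
   all mutants of a protein and are removed, leaving 18 targets. Applying
   the drop twice is an error, as is a zero-variance column discovered at
   normalization time (the error suggests excluding it the same way).
3. **Gap filter.** Mutants whose slots are fewer than `min_gap` residues
   apart are discarded (`min_gap` defaults to 12; a gap of exactly 12 is
   kept). The filter stands in for the structural-solver feasibility limit
   on closely spaced insertions; for a length-L protein it retains
   `sum_{d=min_gap}^{L-1} (L - d)` position pairs.
4. **z-normalization.** Each retained score is standardized to mean 0, sd 1
   across **all** retained mutants of the protein, using the population
   (divide-by-N) standard deviation so the transform is exactly invertible
   and bit-reproducible. Computing the statistics before splitting leaks
   marginal location/scale information into the test sets; this is the
   intended protocol here (the splits module exists to control *key*
   leakage, not marginal statistics), and the stats are stored as JSON so
   predictions can be mapped back to raw energy units.

## Splits

Two generalization probes are carved out before the conventional cut, in a
fixed RNG order (Test2 pairs, Test3 pairs, remainder shuffle) from a single
seed:

* **Test2 — unseen position combinations.** Distinct unordered position
  pairs `(p1, p2)` are drawn at random until their mutants reach the target
  share of the dataset (default 5%); *all* mutants with those pairs go to
  Test2, so no other set ever sees those position combinations.
* **Test3 — unseen residue combinations.** From the remainder, ordered
  residue pairs `(a1, a2)` (ordered because the slots are distinguishable
  under canonical position ordering; 400 combinations) are drawn likewise
  (default 5%). Test3 combinations are guaranteed unseen in
  train/val/Test1; they may occur in Test2, which is itself fully held out.
* **Remainder.** Shuffled and cut 80/10/10 into train/validation/Test1,
  with `floor` sizes for train and val and the leftovers in Test1.

`verify_splits` recomputes disjointness, coverage and both leakage counts
by set algebra and is run by the CLI after every split.

## Model

Each categorical input is embedded (dimension 200; the two position slots
share one table and the two residue slots another — slot identity is
carried by concatenation order). The four embeddings are concatenated
(width 800) and passed through one block of two affine → batch-norm → ReLU
layers of the same width, the block input is added back through an identity
skip connection, and a final linear layer (no output non-linearity) maps to
the 18 targets. With the default configuration at L = 60 this is 1,315,218
learned parameters.

Training minimizes the mean Huber loss (delta 1.0 on the z scale: quadratic
for residuals below one target sd, linear beyond) with the NAdam optimizer
(Dozat's Nesterov-momentum Adam with bias-corrected lookahead; beta1 0.9,
beta2 0.999, eps 1e-8), learning rate 1e-5, batch size 64, at most 100
epochs with early stopping on validation loss (patience 10, best-validation
parameters returned). Batch norm uses mini-batch statistics in training and
running averages (momentum 0.1) in inference, so inference is a pure
deterministic function of (parameters, key).

The forward pass, backpropagation (including the batch-norm backward) and
the optimizer are implemented directly in NumPy (float32). Numerical
choices:

* **Initialization.** Embeddings ~ N(0,1); block weights He-initialized;
  batch-norm scale 1 / shift 0; the output layer is **zero-initialized** so
  initial predictions equal the target mean and early optimization fits a
  linear readout of the initial embedding features before reshaping the
  trunk. At the small fixed learning rate this roughly halves validation
  loss within the epoch budget compared with a He-initialized head.
* **Reproducibility.** All randomness (init, batch shuffling) flows from
  one seed through `numpy.random.default_rng`; repeated runs produce
  identical training logs on the same machine and thread count.
* **Degenerate batches.** A trailing batch of size 1 is skipped (batch norm
  needs at least two samples).

## Evaluation

Performance is the Pearson correlation between predictions and z-scored
targets, per score and per split (undefined correlations — zero variance or
strata with fewer than two mutants — are reported as missing with a
warning, never as 0). Two stratifications of Test1:

* **Secondary structure.** A mutant is a *helix* (*sheet*) case when at
  least one slot lands on an H (E) residue — the slot inherits the label of
  the residue it inserts before — and *neither* when both slots land on C.
  Helix and sheet may overlap; *neither* is disjoint from both; the three
  cover all mutants. Reported stratum sizes make the overlap explicit.
* **Solvent accessibility.** Per-residue SASA/volume ratios are cut at the
  protein-wide 33rd/66th percentiles (linear interpolation between order
  statistics; *low* is strictly below the 33rd, *high* strictly above the
  66th, boundary ties are medium). A mutant is *low_low* / *high_high* when
  both slots are low / high, else *other* — a partition.

## Synthetic benchmark

The generator emulates the statistical shape of structure-derived mutant
score tables with a known ground truth:

    score_k(p1,p2,a1,a2) = f_k(p1) + f_k(p2) + g_k(a1) + g_k(a2)
                           + h_k(a1,a2) + eps,   eps ~ N(0, noise_sd^2)

with a smooth position effect `f_k` (sum of three seeded sinusoids over
1..L), residue effects `g_k` (20 seeded values), and a small pairwise
interaction `h_k` (20x20). Variance budget per score: 0.25 per position
slot, 0.20 per residue slot, 0.10 interaction — about 1.0 total before
noise, so `noise_sd` reads directly on the z scale. The `ref` score is
sequence-only (`g` only, variance 1, zero noise), mirroring the reference
energy term's behaviour; `yhh_planarity` and `dslf_fa13` are emitted as
constant columns so the drop step has something real to remove. Pseudo-
protein annotations use H/E/C runs with geometric run lengths (mean 6,
successive runs always change state) and i.i.d. uniform SASA/volume ratios.

Position effects are smooth in p so unseen-position generalization (Test2)
is learnable but harder than unseen-residue generalization; this lets the
qualitative ordering of the test sets be examined without being forced by
construction.

What the generator does *not* emulate: real energy terms are heavy-tailed,
mutually correlated, and nonlinear in position (steric clashes propagate);
SASA and secondary structure here are independent of the scores, so
stratified correlations on synthetic data probe bookkeeping correctness,
not the physical effect of burial or helix disruption. Passing tests
demonstrate that the pipeline recovers a known landscape under its stated
protocol, not that the learned model transfers to any real protein.

## Benchmark problem sizes

The default function-recovery benchmark uses L = 60, 20,000 random mutants,
noise sd 0.1, and the default model/training configuration (about 7 minutes
on one CPU core). The generalization-ordering check in the test suite uses
a reduced configuration (L = 40, 6,000 mutants, 30 epochs, 3 seeds) and
asserts the Test1 >= Test2 ordering of mean Pearson over the
position-dependent scores with a 0.05 seed-noise tolerance. Unit and
property tests use L = 30..40 with a few hundred to a few thousand mutants.

## Known limitations

* One model per protein; no cross-protein transfer or sequence input.
* Normalization before splitting (see above) is the intended protocol but
  is a deliberate marginal-information leak; a train-only variant would
  need the stats refit on the train split.
* The parameter count of the default configuration depends on L through the
  position table; no configuration is claimed to reproduce any particular
  published parameter total, and `count_parameters` exists to check a
  supplied configuration against an expected count.
* CPU-only by design; no GPU path.
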