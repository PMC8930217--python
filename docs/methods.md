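# Methods

This note records the model, the defaults and why they are what they are,
what the synthetic generator does and does not emulate, and the numerical
choices a maintainer would otherwise have to reverse-engineer.

## Problem setting

Two-class gene-expression classification in the n ≪ p regime: on the order
of a hundred tissue samples against thousands of genes. The package's
reference shape is 2135 genes × 102 samples (52 tumor, 50 normal). At that
ratio most genes are noise, classifiers overfit, and the scientific output
of interest is as much the selected gene subset as the classifier itself.

## Preprocessing cascade

Five label-free steps, default order log → collapse → impute → flat-filter
→ standardize:

- **Log transform.** `log2(v + 1)` on non-missing cells. Raw intensities
  are right-skewed (multiplicative noise); the log makes them roughly
  symmetric. Base 2 with pseudocount 1 is the microarray convention; the
  pseudocount guards zeros. Any cell with `v + shift ≤ 0` is a hard error
  naming the gene and sample — silently clipping would fabricate data.
- **Replicate collapse.** Rows sharing a gene ID are averaged element-wise
  over their non-missing entries; a cell stays missing only if missing in
  every replicate; first-occurrence order is kept.
- **Mean imputation.** Missing cells take their gene's observed mean. This
  is only defensible under missing-completely-at-random, which is exactly
  what the generator plants; informative missingness is out of scope.
- **Flat-pattern filter.** Genes with dispersion (variance by default,
  max−min range optionally) below 1e−6 are dropped. On the log2 scale this
  removes numerically constant rows without touching any real signal. It
  runs before standardization so zero-variance rows never reach the divide.
- **Standardization.** Per gene, subtract the mean and divide by the
  *population* SD (divisor n), making the mean-0/SD-1 postcondition exact
  rather than approximate. Centering is per gene, not per sample: genes are
  the features whose scale variance the step is meant to remove.

Every run emits a provenance record (genes in/out per step, removed IDs)
so a filtered matrix can be audited.

## Selection: chaotic invasive weed optimization

### Encoding and fitness

A weed's position lives in `[0,1]^N`; thresholding at 0.5 yields the gene
mask. This static transfer is the simplest binarization; the threshold is
configurable. The fitness

`α · Δ_R(Y) + β · |Y|/|T|` with `α = 0.99, β = 0.01`

uses weights standard in the wrapper-selection literature: accuracy
dominates and subset size acts as a tie-break. `Δ_R` is the stratified
5-fold cross-validated misclassification rate of a nearest-centroid
classifier on the masked genes. Folds are built once per evaluator from
`cv_seed`, so fitness is a deterministic function of the mask — a
requirement for the exhaustive-search equivalence tests. `cv_repeats`
averages the error over several seeded partitions (default 1; raising it
reduces partition-luck in the error estimate at proportional cost). The
empty mask scores `α·1.0` (worst-case error): treating it as an error would
leave a hole in the search space, and the brute-force oracle shares the
convention. The inner classifier is nearest-centroid because the fitness is
called thousands of times per run; it is implemented as a vectorised
centroid/distance computation, with scikit-learn's `NearestCentroid`
serving as an independent cross-check in the tests. Wrapping the neural
network itself (`inner_classifier="dnn"`) is supported but not the default.

### Colony dynamics

- Initial positions: uniform draws modulated element-wise by consecutive
  logistic-map values (`u = 4`, default start 0.7) and clipped to [0,1].
  The map's ergodicity spreads the initial colony; starts in
  {0.25, 0.5, 0.75} are rejected because they hit fixed points or short
  cycles and destroy the chaotic orbit.
- Seed counts interpolate linearly in fitness rank between `S_max` (best)
  and `S_min` (worst), rounded half-up (half-up is deterministic across
  platforms, unlike banker's rounding of `round()`).
- Dispersal SD decays from 0.5 to 0.01 with nonlinearity exponent 3 over
  `max_iter` iterations; offspring positions are clipped to [0,1].
- Exclusion keeps the `P_max` fittest; ties break toward fewer selected
  genes, then insertion order, so results are reproducible and parsimony is
  favoured at equal error.
- Ranks are recomputed each iteration over the surviving population.
- Stopping is a fixed iteration budget; the best-ever weed is returned and
  the recorded best-fitness trace is non-increasing by construction.

Default budget (`n_weed=10, s_min=0, s_max=5, p_max=30, max_iter=50`)
follows the orders of magnitude in the invasive-weed literature and is
sized for problems of a few hundred genes (~4k fitness evaluations). For
full-scale matrices (~2000 genes) the bundled demo configuration raises
`max_iter` to 150 (~11k evaluations): metaheuristic budgets should scale
with the dimension of the search space.

### Known behaviour of the objective

The scalarised objective rewards the *smallest* subset achieving the
lowest observed CV error. When a handful of strong genes already reach
zero observed error, the size penalty actively prunes further informative
genes; the fitness optimum is then a minimal zero-error subset, not the
complete planted set. Recall of a planted gene set therefore peaks at an
intermediate search intensity and *decreases* as optimization gets better.
This is a property of the objective, not an implementation artifact; users
who want complete gene recovery should lower `β`, raise `cv_repeats`, or
treat the union of near-optimal subsets as the signature.

## Classifier and optimizer

Two ReLU hidden layers, default sizes (64, 32), softmax output, two-way
softmax rather than a single sigmoid to match the multiclass formulation.
Weight init is He-style scaled uniform (`±√(6/fan_in)`), seeded; biases
start at zero. Losses: negative log-likelihood (default; probability
floored at 1e−12 so `−log 0` cannot occur) and half squared error
`‖t − p‖²/2`. For softmax+NLL the output delta is the standard `p −
onehot(t)`; for squared loss the full softmax Jacobian-vector product is
used. Both paths are verified against central differences (step 1e−5,
relative error < 1e−5, float64).

RMSprop: `G_t = 0.9·G_{t−1} + 0.1·g⊙g`, step `−α·g/√(G_t + ε)` with
`α = 1e−3`, `ε = 1e−8`. Decay 0.9 is the canonical choice. Training is
mini-batch (default 16) with seeded shuffling for 200 epochs; per-epoch
loss/accuracy on the full training set (and optionally a validation set)
are recorded. Identical seeds give bit-identical parameters and history.
Epochs/batch/learning-rate have no canonical values for this problem
family; the defaults were fixed by a small sweep on synthetic data at the
generator's default conditions and are deliberately plain.

Non-finite training loss aborts with a diagnostic rather than continuing
on garbage. No regularizers, dropout or architecture search — deliberately
outside this package's scope.

## Evaluation protocol

"Iterations" are repeated seeded stratified 70/30 hold-outs — the only
protocol under which per-iteration metric rows vary while class balance is
preserved. Per iteration, the pipeline is fit on the training split only
(selection seeds and CV seeds derive from the iteration seed) and scored
once on the held-out split. Metrics are computed from exact confusion
counts; 0/0 denominators yield 0 with a warning. Percentages are exported
rounded to 2 decimals; all internal arithmetic is full precision. The ROC
is a threshold sweep over unique scores with ties grouped and AUC by the
trapezoid rule, reported over the test scores pooled across iterations;
scikit-learn's implementations are the independent reference in tests,
never the implementation. The positive class is "tumor".

A leakage guard is part of the test suite: refitting against permuted test
labels must leave the selected mask and the trained parameters
bit-identical, changing only the metric rows.

## Synthetic data: what it does and does not emulate

Gene g in class c is `Normal(μ_g + s_g·Δ·[c = tumor], σ)` on the log2
scale, with baselines `μ_g ~ Normal(7, 1.5)`, noise SD 1, and the planted
shift `Δ` applied only to informative genes with alternating sign — so no
single global mean filter can recover the set. `raw_scale` exponentiates
base 2, producing the right-skewed positive intensities the log transform
targets. Contamination plants exactly what preprocessing repairs:
appended noisy duplicate-ID rows, MCAR missing cells at a fixed rate, and
near-constant rows substituted into non-informative positions.

Defaults mirror the reference study shape (2135 genes, 52/50 samples);
contamination defaults to zero so a default spec is a clean matrix.
Fixture levels used throughout the tests are 1% missing cells, 5 duplicate
IDs, 3 flat genes.

Not emulated: probe-level physics (background, saturation), batch
effects, correlated gene modules, informative missingness, class-specific
variance. Passing tests therefore demonstrate correctness of the
machinery and recoverability of independent planted signals — not
performance on any real cohort, where correlated genes and batch structure
typically make selection harder.

## Problem sizes in the bundled checks

The test suite and the acceptance script run entirely on generated data at
deliberately modest sizes: exhaustive-search comparisons on 8-gene
problems (256 subsets), recovery runs on 200-gene / 120-sample datasets,
and one full-scale 2135 × 102 pipeline with 5 hold-out iterations. These
sizes exercise every code path while keeping a complete run at desk scale
(the whole acceptance script is about a minute on one core).

## Known limitations

- The dispersal-plus-threshold encoding stagnates once positions drift far
  from the threshold: at small σ almost no bits flip, so late iterations
  refine little. A time-varying transfer function would help; it is out of
  scope here.
- Nearest-centroid fitness assumes roughly isotropic within-class noise;
  heavy correlation between genes will mislead the subset-size pressure.
- The evaluation protocol reuses the same samples across hold-out
  iterations; the iteration rows are not independent and their spread
  understates true variance.
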