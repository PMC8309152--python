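# Methods

## Problem and modelling approach

Intrinsic aqueous solubility S₀ is the equilibrium solubility of a
compound's neutral form; it is modelled here as logS₀ in log₁₀ mol/L.
The package implements a QSPR (quantitative structure–property
relationship) pipeline: per-molecule numeric descriptors → feed-forward
network → logS₀, with the general solubility equation (GSE) and a
predict-the-mean null model as baselines, and an explicit
domain-of-applicability (DOA) assessment.  Descriptors are treated
strictly as numeric inputs; the package never computes them from
structures.

## Curation

Literature records arrive as (compound, source, value, unit, optional
molecular weight, optional polymorph label).  Rules:

* Units `molar`, `mg_per_mL`, `ug_per_mL`, `g_per_L` are converted to
  log₁₀ molar (mass units need a molecular weight; missing MW is an error
  naming the record).  `log_molar` passes through.  The unit list is
  closed: unknown units raise rather than guess.
* Polymorph-labelled entries of one compound are ordinary replicates.
* Identical rows (same compound, source, polymorph, value) are rejected as
  data errors rather than silently averaged.
* Replicates are aggregated per molecule by arithmetic mean (default,
  matching how the reference evaluation sets were built), median, an
  explicit most-trusted override table (`strategy="manual"`; no automatic
  trust criterion exists), or kept row-per-replicate (`"all"`).
* Molecules appearing in any test set are removed from training *before*
  aggregation, so the replicate summary reflects the retained molecules.
* Molecules with any undefined descriptor are dropped.

The replicate summary reports the count histogram and the **mean
inter-laboratory SD**: the unweighted mean, over molecules with ≥ 2
replicates, of the per-molecule sample SD (n−1 denominator).  The
estimator choice is the package's own; it is the natural reading of an
"average inter-laboratory standard deviation" and is what the synthetic
generator is calibrated against.  This quantity is the reproducibility
floor: no model can be validated below it on replicated data.

## Feature selection and scaling

Zero-variance means *literal* zero variance (one distinct value); a column
constant up to 1e−15 jitter is kept.  Pruning repeatedly finds the
currently most-correlated descriptor pair with |Pearson r| above the
threshold (default 0.8) and drops the member with the smaller |r with
logS₀|; ties in target correlation keep the alphabetically first name, and
ties in pairwise correlation resolve the alphabetically first pair — the
procedure is deterministic and, because pairwise correlations never
change when a column is removed, order-independent in the common case.
Survivors are ranked by |r with logS₀| and the top k (default 10) are the
model inputs.

Scaling is min–max into (0, 1) using training statistics only, for both
descriptors and target.  Test values falling outside [0, 1] are **not
clipped**: the map is applied verbatim, and the network's logistic output
still bounds the final predictions to the training logS₀ range.

## The network

A standard three-layer perceptron: k inputs (the scaled descriptors), one
hidden layer (default 25 units), one output unit, **logistic activation on
every neuron including the output**.  Loss is mean squared error on the
(0, 1)-scaled target plus an L2 penalty α/(2n)·Σ‖W‖² on the weights
(biases unpenalised), minimised by full-batch Adam (step 10⁻³, β₁ = 0.9,
β₂ = 0.999) for at most 4000 epochs with no early stopping; "iterations"
are full-batch epochs.  Weights are initialised Glorot-uniform from a
seeded generator, so training is bit-reproducible given (data, config,
seed).  Because stochastic restarts matter for a network this small,
performance numbers are reported as means over ≥ 10 seeds wherever they
feed a decision; in practice the strongly regularised network converges to
nearly the same function from every start (seed-to-seed RMSE spread
< 10⁻³ under the default conditions).

The implementation is plain numpy.  A scikit-learn `MLPRegressor` (which
offers a logistic hidden layer but only an identity output) serves as an
independent cross-check in the test suite.

Baselines: the GSE closed form logS₀ = 0.5 − logP − 0.001 (Tmp − 25),
evaluated only where experimental logP and Celsius melting point are
supplied (no imputation, no predicted-logP fallback); and the null model,
which stores the training-mean logS₀.  For a constant prediction c the
metrics obey RMSE² = ((n−1)/n)·SD² + (ȳ − c)², which the package exposes
as `null_rmse_identity` and verifies to 1e−9.

## Metrics and outliers

R² is computed against the evaluated set's own mean (so a foreign constant
prediction gives R² < 0 and the set's own mean gives exactly 0); bias is
mean(experimental − predicted); %±0.5 counts |error| ≤ 0.5 **inclusive**
(the boundary convention is the package's own and is tested).  Outliers
are compounds with |error| *strictly* greater than 2 × the set's own RMSE;
best-predicted compounds have |error| ≤ 0.2 × RMSE.  Leave-out re-metrics
remove listed compounds cumulatively, one per step.

Cross-validation shuffles into k folds (default 10); each compound is
validated exactly once.  Feature selection and scaling are re-fit inside
every training fold by default (leakage-free); `select_within_folds=False`
reproduces the historical protocol of selecting once on the full table.

## Applicability domain

PCA is fitted on the centred — not re-standardised — scaled training
descriptors (they already share the (0, 1) range).  The 95% region on
PC1–PC2 is the set of scores whose Mahalanobis distance under the
training-score covariance (n−1 denominator) is within the χ²(2 df) 0.95
quantile; the ellipse construction is the package's own choice.  Rank-
deficient training data still yields a valid PCA, but the ellipse is
undefined (singular covariance raises at membership time).

The similarity index between two vectors in the m-dimensional unit
hypercube is 1 − ‖a−b‖/√m: √m is the corner-to-corner distance, so the
index lies in [0, 1], equals 1 only for identical vectors, and induces the
same neighbour ranking as raw Euclidean distance.  A difference-of-squares
variant (1 − √(Σ(aᵢ²−bᵢ²))/√m) is available behind `literal=True` for
comparison; its radicand can be negative, in which case NaN is returned —
it is not a metric and is not used anywhere.  √m generalises the
denominator to feature sets of any size.  Vectors outside the unit cube
(unclipped test compounds) are computed as-is and can yield indices below
0 in principle; the DOA report flags them via ellipse membership instead.

Per-compound DOA reports combine ellipse membership, maximum similarity to
any training compound, and the min/mean/max logS₀ of the 10 nearest
training neighbours — low similarity or a neighbourhood whose solubility
disagrees with the compound are both reasons to distrust the prediction.

## Synthetic-study generator

The generator emulates the statistical structure of a curated literature
training set and its two evaluation sets; all defaults are the study
conditions and are not tuning knobs:

* true logS₀ ~ N(−3.4, 1.95²) per molecule (n = 270);
* replicate counts from the histogram {1: 189, 2: 50, 3: 18, 4: 7, 5: 1,
  6: 3, 8: 1, 10: 1} — used exactly when its counts sum to n, otherwise
  sampled from its proportions;
* replicate noise Normal with per-molecule scale `interlab_sd / c4(n)`
  (c4 the Gaussian sample-SD unbiasing constant), so the curation
  summary's mean-of-sample-SDs statistic is unbiased at the configured
  0.78; records are emitted 50/50 in log-molar and µg/mL (synthetic MW
  uniform in [100, 600] g/mol) to exercise unit conversion;
* descriptors from a single latent factor: descriptorⱼ = ρⱼ·z +
  √(1−ρⱼ²)·εⱼ with z the logS₀ standardised by the *training population*
  moments (−3.4, 1.95) for every set, so training and test compounds share
  one descriptor space; ρ defaults to the 10-descriptor profile
  (ALOGP −0.637, nC −0.583, nCIC −0.511, nBnz −0.510, Ui −0.434,
  Me +0.310, RBN −0.224, nN +0.214, nX −0.200, Hy −0.138).  Columns are
  affine-mapped to plausible magnitudes (e.g. ALOGP ≈ 2.3 ± 1.8); the
  profile constants are cosmetic and leave all correlations untouched.
  The latent model implies pairwise descriptor correlations ρᵢρⱼ (≤ 0.37
  here, below the pruning threshold); a full residual-correlation matrix
  can be injected to exercise the pruning rule;
* tight test set: 100 compounds, true logS₀ ~ N(−4.03, 1.27²), observed =
  true + N(0, 0.17²); loose set: 32 compounds, N(−5.49, 2.18²), noise SD
  0.62, with 3 of 32 compounds shifted 4 scale-units out of the training
  descriptor cloud (random sign per coordinate) to emulate sparsely
  populated chemical space — the shifted rows are marked in a `shifted`
  column for testing;
* GSE inputs: melting point ~ N(150, 50²) °C truncated at 25; logP drawn
  with corr(logP, logS₀) = ρ (default −0.8) but located and scaled so the
  regression slope of logP on logS₀ is −1 — logP scatters around the
  GSE-inverse, making the GSE baseline unbiased with RMSE ≈
  sd·√(1/ρ² − 1) ≈ 1.46, as a physically meaningful baseline should be.

One seed drives named `SeedSequence` sub-streams per stage; identical
config + seed gives byte-identical CSVs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real descriptor–descriptor covariance (only the
rank-one structure plus optional overrides), non-Gaussian solubility
tails, unit- or source-correlated measurement error, systematic
inter-laboratory bias (noise is zero-mean), and any actual chemistry —
descriptors are numeric surrogates with no structural meaning.  In
particular the synthetic world is *self-consistent by construction*: the
descriptor–solubility relationship is exactly learnable up to noise, so
absolute error levels on synthetic data speak to the pipeline's
correctness, not to attainable accuracy on real compounds.

## Numerical choices and degenerate inputs

Scaling requires strictly positive ranges (zero-range features/targets
raise; zero-variance columns must be removed first).  Correlation on a
constant column raises.  Aggregating an empty group raises.  `k` larger
than the available descriptors or training compounds raises.  NaN in
network inputs raises before training.  Target-scaling round-trips are
exact to 1e−12; the constant-predictor identity holds to 1e−9; the
mass-unit conversion round-trips to 1e−9 relative.

## Problem sizes used in tests and the acceptance script

Distributional checks use n = 10⁴ molecules (moments, inter-laboratory SD,
ellipse self-coverage) and n = 10⁵ samples (descriptor correlations);
model-level checks run the full 270-molecule study conditions with 10
network restarts and 10-fold cross-validation.  These sizes put Monte-
Carlo error well inside the asserted tolerances while keeping the whole
suite fast enough to run routinely.

## Known limitations

* The network reports no convergence diagnostics beyond the loss curve;
  4000 full-batch epochs are treated as the iteration budget, with no
  early stopping.
* The DOA ellipse is 2-D only; compounds can sit inside PC1–PC2 yet far
  from training data in discarded components (the similarity index
  catches most such cases and both are reported side by side).
* `strategy="manual"` requires an explicit override table; the package
  deliberately encodes no source-trust heuristic.
* Exclusion of compounds "too soluble to measure" is left to upstream
  data preparation; no numeric cutoff is applied.
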