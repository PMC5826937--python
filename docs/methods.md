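# Methods

## The analysis problem

A pooled plasma sample is aliquoted and stored at −20 °C; ten aliquots are
moved to −80 °C (which halts degradation) every 3 days for 30 days, giving
an 11-time-point × 10-replicate design quantified in one LC-MS batch
together with repeated injections of a pooled QC sample and a QC dilution
series at relative concentrations 1, 1/5, 1/10 and 1/50. The analysis
starts from the deconvolved feature table (samples × features, one feature
per retention-time/m-z pair) and asks two questions: *which features change
with storage time*, and *how well does the profile predict storage time* —
the latter answered with an elastic-net-penalized Poisson regression whose
nonzero coefficients double as a ranked biomarker panel.

## QC filtering

Vendor exports mark non-detects as zeros; these are converted to missing
before anything else. Three filters then run in order, each consuming the
previous stage's retained set:

1. **Dilution response.** For each feature, the Pearson correlation between
   intensity and relative concentration over the dilution-series injections
   (pairwise-complete, linear scale). Retained iff r² > 0.5 *and* r > 0.
   The positivity requirement is deliberate: background noise can
   anti-correlate by chance, and "responds to dilution" means intensity
   rising with concentration. Features with fewer than three usable
   dilution points are removed conservatively.
2. **QC repeatability.** %CV = 100·SD/mean over the undiluted QC
   injections (n−1 SD, missing dropped); removed iff %CV > 30 — the
   inequality is strict, so %CV exactly 30 is retained.
3. **Missingness.** Fraction of missing values over study + QC samples
   (blanks are not part of the quantified data); removed iff > 20 %,
   again strict.

All three statistics are scale-free, so rescaling a feature or permuting
samples cannot change a decision (property-tested).

## Preprocessing

KNN imputation (k = 10, nan-aware Euclidean distance normalized by the
number of co-observed features — each missing cell becomes the mean of the
feature's values in the k nearest samples), then constant-sum
normalization (each sample divided by its total intensity), then the
generalized log

  g(x) = log₂((x + √(x² + a²)) / 2),

then autoscaling (per-feature mean 0, SD 1, n−1 convention; constant
columns are zeroed with a warning and the centering/scaling constants are
stored for inverse mapping).

**Choice of the glog parameter a.** After constant-sum normalization the
entries are on the order of 1/p (~10⁻³ for ~10³ features). The transform
behaves like log₂(x) only for x ≫ a and becomes *affine* for x ≪ a; a
fixed a = 1 on the normalized scale therefore disables variance
stabilization entirely — and, worse, leaves exponentially trending
intensities convex in time, which biases downstream selection toward
decaying features. The pipeline therefore defaults to `a = "auto"`: one
tenth of the median positive normalized intensity, putting the bulk of the
data in the logarithmic regime while keeping g finite at zero. The
standalone `glog_transform` keeps an explicit scalar parameter (default 1)
for use on raw-scale data.

Order of operations is impute → normalize → glog → autoscale; imputation
first matches the convention of web-based metabolomics platforms and both
orders are available for sensitivity checks.

## Univariate statistics

Per feature, a one-way within-subject (repeated-measures) ANOVA with the
replicate aliquot as subject: SS_total = SS_subject + SS_time + SS_error,
F = MS_time/MS_error with (k−1, (k−1)(n−1)) degrees of freedom. In the
real study the aliquots are exchangeable rather than true subjects; the
synthetic generator gives each replicate a small persistent offset so the
within-subject pairing is honest on test data. Features with zero
SS_time are reported as F = 0, p = 1 (never NaN) so downstream ranking is
total. Paired t-tests compare each day against day 0, paired by replicate;
zero-variance differences map to t = ±∞ (p = 0) or t = 0 (p = 1).
Benjamini–Hochberg adjustment is applied across features — per day for the
pairwise tests, and per ionization mode when modes are analyzed separately
(modes are always independent runs). The BH step-up is the standard one
(via statsmodels), validated against hand-computed cases and a
1000-simulation global-null calibration.

## Moderated Hotelling T² ranking

Each feature's replicate profiles (n × k) are mapped through successive
-difference flatness contrasts C ((k−1) × k); with mean x̄_C and covariance
S_C of the contrasted profiles, the statistic is

  T² = n · x̄_Cᵀ S̃⁻¹ x̄_C,  S̃ = (ν Λ + (n−1) S_C) / (ν + n − 1),

where Λ is a *shared diagonal prior in contrast space*, estimated as the
across-feature mean of per-feature contrast variances, and ν defaults to
k − 1. This is the empirical-Bayes moderation needed for the n = 10,
k = 11 design, where the classical statistic (ν = 0) is singular because
n − 1 < k − 1. At ν = 0 (and n − 1 ≥ k − 1) the statistic reduces exactly
to the classical one-sample Hotelling T² on contrasts, and the classical
value is invariant to the choice of full-rank flatness contrast (both
property-tested). T² is location-invariant and the ranking is invariant to
rescaling the whole matrix; ties are broken by feature id so ranks are
deterministic. Only the one-sample (single-condition time course) setting
is implemented. Note that features with large *erratic* day-to-day shifts
legitimately attain high T² — the statistic measures departure from
flatness, not monotone trend; separating the two is precisely the job of
the regression stage.

## Elastic-net Poisson regression

The storage day y ∈ {0, 3, …, 30} is modeled as Poisson with
μ = exp(β₀ + xᵀβ) and the coefficients minimize

  −(1/N) Σᵢ [yᵢ(β₀ + xᵀᵢβ) − e^{β₀+xᵀᵢβ}] + λ[(1−α)‖β‖²/2 + α‖β‖₁],

intercept unpenalized, inputs pre-centered by autoscaling (the solver
*enforces* centered columns rather than silently standardizing).

**Solver.** Outer IRLS: weights w = μ, working response
z = η + (y − μ)/μ. Inner cyclic coordinate descent with soft-thresholding
on the weighted quadratic subproblem, using active-set iteration: converge
on the current active set, then one vectorized KKT screening pass over all
coordinates absorbs violators. Convergence at max |Δβ| < 1e−7 (up to 10⁵
sweeps); every fit is certified post hoc by the subgradient (KKT)
conditions at tolerance 1e−5, and the solution objective matches an
independent general-purpose minimizer to ≤ 1e−6 on small instances. The
linear predictor is capped at ±30 before exponentiation as an overflow
guard; the cap is inactive at converged solutions on well-scaled data. The
inner loop is JIT-compiled with numba when available; a semantically
identical numpy fallback is kept and tested against it.

**Path and tuning.** λ_max = max_j |⟨x_j, y − ȳ⟩| / (N α) is the smallest
penalty whose null model satisfies the KKT conditions (α < 0.001 uses the
0.001 surrogate); the grid is log-spaced over 100 values down to
λ_max·10⁻⁴ (10⁻² when p ≥ N), fitted with warm starts. Cross-validation
records held-out Poisson deviance per λ; λ_min minimizes the mean CV
deviance and λ_1se is the largest λ within one standard error (computed
across fold means) of that minimum. Both leave-one-out and k-fold are
implemented; the pipeline default is 10-fold (seeded), which on the
default experiment selects the identical model to LOO at a fraction of the
cost, and LOO remains available as `cv_folds="loo"`. The default selection
rule is λ_1se (conservative; λ_min is always reported alongside). The α
mixing grid {0, 0.25, 0.5, 0.75, 1} can be screened by CV deviance with
ties broken toward 0.5; the pipeline default fixes α = 0.5 (equal ridge
and lasso weight), with screening available via `screen_alpha`. CV loss is
the deviance; RMSE/RMSEP are computed only for final-model evaluation.

**Two fits, two purposes.** The pipeline fits the model twice: a
*prediction* fit on a 75/25 train/test split stratified by storage day
(⌈0.75·n_day⌉ per day to train) whose held-out RMSEP and squared Pearson
R² (with the t-transform p-value) measure predictive quality against the
R² > 0.8 acceptance bound; and a *selection* fit on all study samples,
whose nonzero coefficients, ranked by |βⱼ| (ties by feature id), form the
reported biomarker panel and feed the heat map and PCA summaries. Feature
selection benefits from all the data; honest error estimation needs the
held-out split — conflating the two would either waste a quarter of the
data on selection or leak the test set into it. No standard errors or
p-values are attached to penalized coefficients (they are biased
estimators); stability can instead be assessed by re-running CV across
seeds.

## Synthetic data generator

Per-feature model on the log2 scale:
baseline + slope·day + replicate offset + noise, exponentiated to
intensities. Defaults (chosen once as plausible for LC-MS plasma
profiling; the emulated study reports no raw data to calibrate against):

| parameter | default | meaning |
|---|---|---|
| n_features | 1500 | features per ionization mode |
| days | 0,3,…,30 | 11 time points |
| n_replicates | 10 | aliquots per day |
| n_increasing / n_decreasing / n_erratic | 30 / 30 / 30 | planted classes |
| slope_range | 0.03–0.10 log₂/day | 0.9–3 log₂ units over 30 d (~2–8×) |
| replicate_noise_cv | 0.20 | multiplicative lognormal noise |
| replicate_offset_sd | 0.05 log₂ | persistent per-aliquot offset |
| erratic_shift_sd | 0.5 log₂ | i.i.d. day-level shifts, zero trend |
| qc_n_injections | 5 | undiluted QC replicates |
| qc_noise_cv / noisy_qc_cv | 0.10 / 0.60 | QC injection CV, good vs noisy class |
| dilution factors | 1, 0.2, 0.1, 0.02 | QC dilution series |
| frac_background / frac_noisy_qc | 0.30 / 0.10 | filter-target classes |
| missing_rate | 0.05 | MCAR zeros among study samples |
| baseline log₂ | N(17, 1.5) | intensity scale |

Erratic features receive i.i.d. day-level mean shifts with no linear
trend; background features ignore the dilution factor; noisy-QC features
have inflated QC injection CV. Missingness is MCAR by default (an optional
low-intensity-biased mode exists) and is written as zeros, the vendor
export convention. Identical seeds give byte-identical tables.

What the generator does **not** emulate: retention-time drift, injection
-order batch effects, adduct/isotope structure, censored (intensity
-dependent) missingness by default, inter-individual variability (the
design pools donors deliberately), and any correlation between features
beyond that induced by the shared day/replicate structure and constant-sum
normalization. Passing recovery tests therefore demonstrates correctness
of the machinery under the stated generative model, not performance on
real data.

A note on compositional effects: constant-sum normalization transmits the
planted trends into *all* features (when trending features grow, the
normalized share of every other feature shrinks), so stable features show
small induced anti-trends and the univariate significant counts on
synthetic data are much larger than a per-feature null would suggest. This
is a faithful property of total-intensity normalization, not a bug.

## Numerical conventions and edge cases

- SDs use the n−1 convention throughout; %CV likewise.
- Degenerate zero-variance cases return finite statistics (F = 0/p = 1,
  t = 0 or ±∞) rather than NaN.
- Poisson deviance defines y·ln(y/μ) = 0 at y = 0 and requires μ > 0.
- The moderated T² raises a descriptive error only in the genuinely
  singular case ν = 0 with n − 1 < k − 1.
- PCA scores come from the SVD of the column-centered matrix with a
  deterministic sign convention (largest-magnitude loading positive).
- All stochastic steps (generator, fold assignment, train/test split) are
  driven by explicit seeds; rerunning a pipeline config is byte-identical.

## Problem sizes used in the shipped checks

The acceptance script runs the full default experiment (1500 features,
110 study samples) once plus ten replicate experiments for the recovery
median, 50 small solver-oracle instances (N ≤ 30, p ≤ 10), and a
500-feature global-null ANOVA calibration — sizes chosen so the whole
script completes in minutes on one CPU while still exercising every stage
at the study's own design dimensions.

## Known limitations

- Only the one-sample time course is supported (no treatment × time
  interactions).
- The λ_1se rule is deliberately conservative: on highly collinear
  trending panels it recovers a predictive subset rather than every
  trending feature (recall across replicate simulations is typically
  0.4–0.5 at the default conditions, with precision 0.75–0.9).
- Poisson regression treats day counts as unbounded; predictions can
  exceed 30 days.
- No instrument-drift or batch correction; the artifact starts at the
  deconvolved, aligned feature table.
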