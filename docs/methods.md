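# Methods

This note documents the models, conventions and design choices behind
`rbcforecast`, in the order the pipeline runs.

## Data model

A dataset is a complete cube of concentrations indexed by
(metabolite, replicate, time) on one shared, strictly increasing grid of
sampling days. Metabolites are keyed by (metabolite_id, compartment) —
intracellular and extracellular measurements of the same compound are
distinct entries. Units are opaque: no normalisation, log-transformation or
unit conversion is applied anywhere.

Missing cells are a hard load error, never imputed. Every downstream
statistic (per-sample regression, per-time-point median, per-step
differences) assumes the full grid, and silent imputation would bias all of
them; a user who wants to drop a day does so explicitly with
`exclude_timepoints`, which removes whole grid days.

The CSV dialect is tidy UTF-8 with header
`metabolite_id,compartment,replicate_id,time_days,concentration`,
`compartment ∈ {intracellular, extracellular}`. Floats are written with 17
significant digits and re-parsed with round-trip precision, so
write-then-read reproduces the in-memory dataset bit-for-bit.

### Quality-control screen

`flag_anomalous_timepoints` is an advisory reconstruction of manual artifact
screening: for each extracellular metabolite it computes the across-replicate
coefficient of variation (CV) per time point and flags a point whose CV
exceeds `cv_ratio_threshold` (default 3) times the median CV of the other
points. A 1e-9 absolute floor ignores numerically-zero CVs from identical
replicates. Flagging never excludes — exclusion stays an explicit user
action, so the documented path to handling a known-bad day is
`excluded_days` in the run config.

### Replicate split

Replicates are partitioned uniformly at random into equal halves (odd counts
give training the extra bag) by a dedicated seeded generator: changing any
other stage's seed never moves the split.

## Output-Error models

The model class is

y(t) = Σᵢ [Bᵢ(q)/Fᵢ(q)] uᵢ(t − nk) + e(t),  B(q) = b₁ + … + b_nb q^−(nb−1),
F(q) = 1 + f₁ q⁻¹ + … + f_nf q^−nf,

where the shift `q⁻¹` acts on **sample index**, not clock time, even though
the storage grid is non-uniform (3–4 day intervals). The polynomials carry no
Δt, and the selected configuration (nb = 1, nf = 0, nk = 0) uses no lags at
all, so the choice only affects optional lagged configurations.

Pre-sample values of inputs and outputs are zero (zero initial conditions),
both in simulation and in the regression rows built for estimation, keeping
the two exactly consistent and the estimator closed-form.

With nf = 0 the model is finite-impulse-response and linear in its
coefficients; `fit_oe` is ordinary least squares of the output on lagged
inputs. With nb = 1, nk = 0 and no intercept this is exactly multiple linear
regression through the origin on contemporaneous inputs. An optional
intercept is exposed (`include_intercept`) because the canonical model has no
constant term, yet an intercept-free static model *is* regression through the
origin; users wanting the "simple linear regression with intercept"
comparator can enable it. Estimation for nf > 0 (iterative prediction-error
minimisation) is deliberately out of scope; simulation supports it so the
model family's behaviour can still be explored.

Rank-deficient designs (collinear biomarkers) return the minimum-norm
solution with a logged warning instead of erroring: the downstream ensemble
median damps individual unstable members.

Where many targets share one input set (cross-validation), coefficients are
solved for all targets in one batched least-squares call. The regressor
matrix depends only on the inputs, so this is numerically identical to
per-target fitting (verified by a dedicated test).

## Ensembles and consensus prediction

One model is fitted per training replicate per target (10 members for the
default 20-bag study). Prediction for a test replicate runs every member on
that replicate's biomarker profiles and takes the per-time-point median; for
an even member count the median is the mean of the central pair. The
interface accepts biomarkers only — measured target profiles enter solely in
scoring — so test information cannot leak into a forecast.

A note on robustness: the median discards a wildly corrupted member exactly
when that member does not sit in the central pair. With an even count,
pushing a below-centre member to the extreme shifts the central pair by one
order statistic, so the consensus can move — but never outside the range of
the remaining members. When members agree (noiseless data), the consensus is
exactly invariant to corrupting any single member.

Consensus values are clipped at zero for SMAPE scoring only (the linear model
is not sign-constrained; SMAPE is defined on non-negative profiles). Stored
consensus profiles are the raw medians.

## Evaluation

SMAPE is implemented exactly as the per-point ratio |yₜ − ŷₜ| / (yₜ + ŷₜ)
averaged over time points — no factor ½ in the denominator and no ×100, so
scores live in [0, 1] and percentages are display formatting. An epsilon
(1e-12) guards the denominator so a 0/0 pair contributes 0. Per-metabolite
scores are the mean consensus SMAPE over test replicates; the global summary
is the median of those per-metabolite means ± their sample standard
deviation (sd is one dispersion convention among several; it is labelled
wherever reported).

The train/test divergence screen runs a Welch (unequal-variance) two-sample
t-test per (metabolite, time) cell — safer than a pooled test under
between-bag heterogeneity — with Benjamini–Hochberg FDR adjustment over all
cells jointly. A cell is flagged only when both adjusted p < 0.05 and the
percent difference of means (relative to the pooled mean) exceeds 20%.
Cells with zero variance on both sides get p = 1 when the means agree and
p = 0 when they differ.

## Random-walk benchmark

The null for each metabolite is a naive random walk: per-step increments are
zero-mean Gaussian with standard deviation estimated as the root mean square
of all consecutive differences pooled over the testing replicates (squared
differences are sorted before summation so pooling is exactly order
invariant). Walks take one step per grid interval, unscaled by interval
length — the step size was estimated on the same grid, so the conventions
cancel. Starts are drawn uniformly from the pool of measured first-time-point
values of the testing replicates, and walks are clipped at zero step-by-step
(toggleable; the variance-calibration test disables it).

Each walk is scored exactly like the model: mean SMAPE against every testing
replicate's measured profile. The empirical p-value is the fraction of the
10,000 walks scoring *strictly* lower than the model's mean consensus SMAPE
(ties do not count as outperforming); significance is p < 0.05. Each
metabolite's walk stream is seeded by (benchmark seed, metabolite index), so
results are independent of processing order. Which measured profile a walk
should be scored against is a genuine modelling choice; scoring against the
mean over test replicates mirrors how the model's own comparator aggregates
its ten predicted profiles.

Calibration: when the "model" is itself a draw from the walk process its
empirical p-value is uniform on (0, 1) (checked by a seeded
Kolmogorov–Smirnov test), and a perfect predictor always gets p = 0.

## Biomarker-subset selection

All C(|candidates|, k) subsets are enumerated lexicographically and scored by
leave-one-replicate-out cross-validation on the training half: ten folds for
ten training bags, the only partition of ten replicates into ten folds that
keeps whole time series intact (splitting within a profile would leak
temporal information). Each fold trains per-replicate ensembles on the
held-in bags with the subset as inputs and scores consensus predictions for
the held-out bag; the subset score averages uniformly over folds and target
metabolites. Candidate biomarkers outside the subset are excluded from the
target pool — they are rival inputs, not forecasting targets. The selector
returns the best subset plus every subset within an absolute tolerance
(default 0.01 on the [0, 1] SMAPE scale) of the best, supporting
"within one percentage point of the top panel" reasoning; ties break
lexicographically.

Model-order selection reuses the same cross-validation to compare candidate
(nb, nf, nk, intercept) configurations, breaking ties toward fewer free
coefficients.

## Synthetic data generator

The generator emulates the statistical shape of a 45-day, 20-bag storage
study: 14 nominal sampling days (0, 3, 7, 10, 14, 17, 21, 24, 28, 31, 35,
38, 42, 45), 5 extracellular biomarkers, 85 "signal" targets and 6
pure-noise targets (96 metabolites total).

**Biomarkers** follow deterministic three-phase piecewise-linear templates:
two interior breakpoints on grid knots, monotone decay or accumulation, with
most of the total change concentrated in one phase. Breakpoint windows are
staggered across the panel and the dominant phase rotates, so different
biomarkers transition in different storage phases — as real storage-lesion
markers do (glucose falls early and steadily, purine catabolites accumulate
late). This also keeps the five input profiles mutually identifiable rather
than collinear, which is what makes coefficient recovery a well-posed test.
Scales are drawn from a common range (5–15) so no input is drowned by the
others.

**Replicates** ("bags") multiply every profile by a lognormal(0, bag_sd)
factor — bag variation is scale-like — and add Gaussian measurement noise
proportional to the template scale, truncated at zero (truncation, not
resampling: it matches concentration semantics and the SMAPE epsilon handles
zeros downstream).

**Signal targets** are static linear mixtures of the measured biomarker
profiles with positive weights drawn once per target from coeff_range
(default 0.2–1.0), plus proportional noise, truncated at zero — the
generative truth matches the selected model form, so parameter recovery is
exact in the noiseless limit. An optional one-sample-lag mixing mode
exercises input-delay handling.

**Noise targets** are trend-free positive noise around a constant level.
Their per-replicate level factors are drawn independently of the biomarkers'
bag factors: sharing the bag factor would couple their level to the inputs
and make them genuinely predictable, defeating their role as planted
unpredictability.

**Day-31 artifact** (optional): across-replicate deviations of every
extracellular measurement at day 31 are inflated tenfold, mimicking a
mid-storage acquisition artifact; the planted cells are recorded in the
ground truth so the QC screen can be validated against them.

Defaults noise_sd = 0.05 and bag_sd = 0.1 are plausible for quantified
metabolomics but are conventions, not estimates of any particular
instrument; both are exposed. What the generator does **not** emulate:
mechanistic RBC metabolism, real concentration magnitudes or metabolite
identities, heteroscedastic or correlated measurement error, missing data,
or nonlinear biomarker–target relationships. Tests passing on this generator
therefore demonstrate the pipeline's correctness and its statistical
behaviour under its own model assumptions — not performance on any real
storage dataset.

## Seeding and determinism

One global seed drives a run. Every stage (synthesis, split, benchmark) and
every per-metabolite Monte-Carlo stream derives its own child seed by
hashing (global seed, fixed stage tag), so adding stages or reordering
metabolites never perturbs other streams. Identical configurations produce
byte-identical output files.

## Problem sizes used in the test suite

The acceptance checks run at study scale: 96 metabolites × 20 replicates ×
14 (or 13) time points, 10,000 walks per metabolite; seed-replication checks
(coefficient recovery, noise-target false-positive rates) use 20 seeds and
the null-calibration check 200 repetitions of 1,000 walks. The exhaustive
selection evaluates all 56 five-of-eight panels with 10-fold
leave-one-replicate-out CV.

## Known limitations

- Estimation covers only the FIR (nf = 0) family; autoregressive OE models
  can be simulated but not fitted.
- The even-count median's robustness caveat above: one corrupted member can
  move the consensus within the remaining members' envelope.
- The divergence screen's 20% practical-relevance gate and the CV tolerance
  are conventions on the pooled-mean / absolute-SMAPE scales respectively;
  other conventions (MAD, relative tolerance) are not implemented.
- The random-walk null ignores drift and autocorrelation by construction;
  it is a baseline for "better than noise" claims, not a competing model.
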