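# Methods

This note documents the models and conventions implemented in
`sleepeval`, the choices made where a convention was genuinely open,
and what the synthetic studies do and do not establish.

## Data model

All computation happens on a uniform epoch grid (30 s by default;
other uniform grids are accepted). A hypnogram stores canonical stage
tokens W/N1/N2/N3/REM plus the non-stage codes MOVEMENT and UNKNOWN;
legacy R&K N4 is merged into N3 at parse time, and token resolution is
case-insensitive over the documented dialects (numeric 0–5 codes,
letter codes, `?`). Non-stage epochs are *masked*: every per-epoch
operation uses only epochs unmasked in **all** of its inputs, and
masked gaps break runs (no transition or awakening is counted across
one). Hypnodensity rows must be non-negative and sum to 1; deviations
up to 1e-6 are silently renormalized (float serialization noise),
larger ones raise, so corrupt files fail loudly. Files use fixed
column order W,N1,N2,N3,REM and 9-significant-digit floats, making
write/read a numerical identity to ≤1e-9.

## Ensembling and metrics

Soft voting averages member probability rows per epoch; discretization
takes the per-epoch argmax with ties going to the lowest stage index
(or to an external reference label when supplied). Channel fusion uses
a per-epoch majority vote; ties are broken by summed member
probabilities when available, else by the fixed stage-priority order.

Agreement metrics come from the pooled 5×5 confusion matrix: accuracy;
Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from the marginal products
(defined as 1 when both sequences are the same single constant class,
where the formula is 0/0); per-class F1 = 2TP/(2TP+FP+FN); macro-F1 as
the unweighted mean over classes. A class absent from both sequences
is excluded from the macro average; a class present in exactly one
scores 0. Recording-level aggregation reports the unweighted mean ± SD
across recordings; dataset-level aggregation pools confusion matrices
over all epochs.

Method comparisons use one-sided Wilcoxon signed-rank tests with zero
differences dropped. The null is exact for n ≤ 25 without rank ties;
with ties and n ≤ 15 the tail is enumerated over all 2^n sign
assignments of the midranks; larger samples use the normal
approximation with continuity and tie corrections. Holm's step-down is
applied over exactly the comparisons requested in one call (the caller
owns the family), and effect sizes are r = Z/√N with N the non-zero
pairs.

## Consensus

The consensus profile, soft-agreement, majority consensus hypnogram,
soft-consensus and ACS follow the definitions in the README. Open
conventions resolved here: a scorer masked at an epoch simply drops
out of that epoch's vote sum (epochs with no voters are masked);
dataset-level reliability is the unweighted mean of per-recording
soft-agreements; reliability ties break by scorer id, so rankings are
deterministic; consensus tie-breaks use the *recording's own*
reliability ranking while the model-evaluation scorer set uses the
dataset-wide top 4.

## Uncertainty and disagreement prediction

Entropy uses the natural logarithm (maximum ln 5 ≈ 1.609 nats) with
0·log 0 := 0. Pairwise cosine distances are computed for all unique
member pairs per epoch; their mean/SD/max may be compressed to a first
principal component after per-column standardization (zero-variance
columns are dropped with a warning; the score sign is oriented to
correlate positively with the mean-distance column).

Transition proximity is measured against a consensus hypnogram: an
epoch is "near" when the time gap between its interval and the nearest
stage-change boundary is strictly below the window (60 s default, i.e.
two epochs each side at 30 s); the two epochs touching a boundary are
always flagged, which keeps the zero-window limit meaningful.

The disagreement classifier is an unpenalized maximum-likelihood
logistic regression (tolerance 1e-8; perfectly separable folds fall
back to a tiny ridge with a warning) on standardized features, under
leave-one-recording-out cross-validation. Standardization parameters
are estimated on the training folds only, avoiding leakage into the
held-out recording. Folds whose held-out recording contains a single
label class have no defined AUC and are skipped but reported; the
headline number is the unweighted mean AUC over valid folds.

## Clinical markers

Marker definitions are under-specified in common usage, so the package
fixes them explicitly: sleep onset is the first unmasked non-W epoch;
TST is the summed duration of N1/N2/N3/REM epochs (so stage-duration
deltas always sum to the TST delta); WASO counts W strictly between
onset and the last sleep epoch; REM latency runs from onset to the
first REM epoch; an awakening is a maximal unmasked W run strictly
inside the sleep period; transitions are label changes between
adjacent unmasked epochs within [onset, last sleep epoch]. Awakening
and transition rates are normalized by TST in hours — the common
clinical convention — which also makes them invariant to trailing wake
appended after the final sleep epoch. Sleep efficiency is TST over
total recording time. Undefined markers (REM latency without REM,
rates with TST = 0) are NaN, never exceptions, and NaN propagates
through marker differences.

## Distributional bias audit

Bounded performance metrics are modeled with the zeros-and-ones
inflated Beta (BEINF) in its mean/dispersion parameterization:
Beta shapes a = μ(1−σ²)/σ², b = (1−μ)(1−σ²)/σ² on (0,1), point masses
p0 = ν/(1+ν+τ), p1 = τ/(1+ν+τ); links logit(μ), logit(σ), log(ν),
log(τ). Link-scale coefficients are therefore directly interpretable
against published audit tables. Marker differences use a Gaussian
location-scale model (identity/log links); a heavier-tailed shape
extension was considered and left out — the location-scale Gaussian is
the part the audit interprets, and nothing downstream consumes a shape
parameter.

Covariate coding is fixed: age centered at 50 years, gender binary
with female = 0, AHI/10, PLMI/10. Age enters μ and σ through a cubic
B-spline with 10 equally spaced interior knots over the observed range
and a second-order difference penalty (P-spline); the basis is
reparameterized to exclude the constant function so it coexists with
the intercept, and the smoothing parameter is selected by GAIC over
the log grid 10⁻³…10³. ν and τ are intercept-only: boundary outcomes
are rare by construction, and their intercepts have closed-form
multinomial MLEs from the boundary counts. With zero boundary counts
the MLE sits at −∞; the fit flags these as not estimable rather than
inventing a finite value.

Estimation maximizes the (penalized) likelihood by backfitting: the μ
and σ coefficient blocks are alternately re-optimized (BFGS with
analytic gradients; digamma identities for the Beta block) until the
penalized log-likelihood improves by less than 1e-6, with at most 200
outer iterations. Because each block update is itself a full inner
optimization, the objective is non-decreasing across iterations — a
property the tests assert. Standard errors come from the inverse
observed information of the joint (μ, σ) block; spline effective
degrees of freedom use tr[(H + λP)⁻¹H] on the spline sub-block.

Model selection is greedy forward stepwise on GAIC = −2ℓ + k·edf,
first over μ terms, then σ terms, from candidates {age spline, gender,
AHI/10, PLMI/10}; ν, τ never receive covariates. The default penalty
is k = 2 (AIC-like) and is configurable. Note that with eight
add-a-term opportunities, k = 2 retains at least one spurious term in
a null simulation more often than not (the per-term chance-retention
probability is P(χ²₁ > 2) ≈ 0.157); the package's selection
simulations therefore run at the BIC-like k = log n, where the
intercept-only model is kept in ≈80% of null replicates, matching
chi-square theory.

## Synthetic data

The generator emulates the three layers of a multi-annotated staging
dataset. Ground truth is a first-order Markov chain over the five
stages; the shipped default dynamics use high self-transition
(0.85–0.95) and plausible W→N1→N2→N3 / N2→REM routing — a convenience
fixture, not a cohort estimate. Scorers relabel each epoch through a
row-stochastic confusion matrix, switching to a noisier matrix within
a window around true stage transitions; this reproduces the empirical
concentration of inter-scorer disagreement at stage boundaries.
Models emit per-epoch Dirichlet draws centered on a
(confusion-resampled) true stage, with a concentration parameter
controlling sharpness, an optional softmax temperature for
miscalibration, and an optional near-transition regime (separate
confusion, reduced concentration). The near-transition model regime is
a deliberate extension: without it model uncertainty would be
uniformly distributed in time, whereas real staging models are least
confident at boundaries, and the transition-stratified analyses would
have nothing to detect.

The covariate/outcome generator draws age uniformly over 0–88 years,
gender with 65% male, and AHI/PLMI from gamma distributions with
mean/SD 17.7/19.2 and 12.1/21.9 events/hour — summary statistics of a
large heterogeneous clinical registry — and samples outcomes from the
implied inflated-Beta or Normal regression.

All generators are pure functions of (parameters, seed). A single
integer seed fans out through `numpy` seed-sequence spawning with one
substream per scorer/model/component, so enlarging a panel never
perturbs existing members' draws.

A limitation of all of this: synthetic scorers are conditionally
independent given the truth and share one confusion model, whereas
real scorers have correlated, idiosyncratic styles; synthetic
hypnograms are first-order Markov, whereas real sleep architecture has
cycle-scale structure. Passing tests therefore establish the
correctness and internal calibration of the estimators, not claims
about any particular clinical cohort.

## Study conditions and problem sizes

The prepackaged validation studies fix their conditions in
`sleepeval.studies`: coefficient recovery simulates n = 2000 outcomes
per replicate over 20 replicates from the published macro-F1
generating model (logit μ = 1.12 − 0.06·gender − 0.05·AHI/10,
logit σ = −1.51, log ν = −22.54, log τ = −22.63), judging recovery on
the estimable μ/σ blocks at 3 estimated SEs; disagreement prediction
uses 12 recordings × 480 epochs with 5 scorers and 5 models under the
default transition-localized noise; the ensembling-benefit study uses
20 replicates of 10 heterogeneous members (accuracy 0.78–0.88 with
member-specific error patterns, concentration 8) on 960-epoch nights.
Selection simulations use the Normal family at n = 150 with a coarse
smoothing grid. These sizes were chosen as the smallest at which the
Monte-Carlo properties under test are stable.
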