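# sleepeval

Evaluation machinery for automatic sleep staging: soft-voting ensembles,
multi-scorer consensus and agreement metrics, ensemble-uncertainty
analysis, hypnogram-derived clinical markers, and distributional
regression for bias auditing — all runnable on synthetic multi-scorer
data, with no polysomnography download or trained network required.

## Who this is for

Sleep-staging pipelines assign one of five AASM classes (W, N1, N2, N3,
REM) to each 30-second epoch of a night. Comparing such pipelines
fairly is harder than training them: human scorers disagree with each
other (especially near stage transitions), clinical markers derived
from hypnograms inherit staging errors, and model performance drifts
with age, gender and comorbidity indices. This package provides the
statistical toolkit for those comparisons, aimed at researchers
evaluating staging models or scorer panels.

## The models and statistics at its core

**Soft-voting ensemble.** Given M per-epoch probability distributions
ŷ_m^t over the five stages, the ensemble output is their element-wise
mean, ŷ_E^t = (1/M) Σ_m ŷ_m^t.

**Probabilistic consensus and soft-agreement.** With S scorers, the
consensus profile for scorer s at epoch t is
ẑ_s^t = Σ_{i≠s} ŷ_i^t / max(Σ_{i≠s} ŷ_i^t) — the one-hot votes of the
*other* scorers normalized so the modal stage(s) score 1. Soft-agreement
is the average of ẑ_s^t at the scorer's own label,
(1/T) Σ_t ẑ_s^t[y_s^t] ∈ [0, 1], and drives reliability rankings,
consensus tie-breaking and the selection of the top-4 scorer set used
to evaluate automatic models.

**Hypnodensity similarity (ACS).** Two probability-over-stages
sequences are compared by the mean per-epoch cosine similarity.

**Ensemble uncertainty.** Per-epoch Shannon entropy (natural log,
maximum ln 5) of the soft-vote, and the set of pairwise cosine
distances D^t = {1 − sim(ŷ_m^t, ŷ_n^t) : m < n} summarized by
mean/SD/max (optionally compressed to a first principal component).
These features predict epoch-level scorer disagreement in a logistic
model under leave-one-recording-out cross-validation.

**Clinical markers.** TST, WASO, stage durations, REM latency,
awakenings/hour, transitions/hour and sleep efficiency from a
hypnogram; bias audits model the differences prediction − reference.

**Distributional bias audit.** Bounded metrics (macro-F1, class F1)
follow a zeros-and-ones-inflated Beta distribution with logit links on
location μ and scale σ and log links on the boundary-inflation odds
ν, τ; marker differences follow a Normal location-scale model
(identity/log links). Age enters via a penalized cubic B-spline
(years above 50), gender (female reference), AHI/10 and PLMI/10 enter
linearly; terms are chosen by GAIC forward stepwise selection.

**Paired comparisons.** One-sided Wilcoxon signed-rank tests (exact
null for small samples), Bonferroni–Holm correction, effect size
r = Z/√N.

## A worked example

`examples/ensemble_and_score.py` simulates a night, four noisy
probabilistic stagers, and their soft-voting ensemble:

```
member macro-F1 against the true hypnogram:
  model1: MF1 0.850  acc 0.865
  model2: MF1 0.817  acc 0.838
  model3: MF1 0.842  acc 0.859
  model4: MF1 0.831  acc 0.850
soft-voting ensemble: MF1 0.971  acc 0.975  kappa 0.967
```

Each member misclassifies ~15% of epochs, but their errors are
independent, so averaging the probability rows before taking the
argmax removes most of them: the ensemble macro-F1 (0.971) clears the
best member (0.850) by a wide margin. The other scripts in `examples/`
walk through consensus building, uncertainty-based disagreement
prediction, clinical markers and the bias audit the same way.

A thin CLI mirrors the library for shell use
(`sleepeval simulate|score|ensemble|consensus|uncertainty|markers|bias-audit`);
see `sleepeval --help`.

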