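"""Prepackaged synthetic validation studies.

Each function here wires several modules into a small, fully seeded
end-to-end experiment whose study conditions are fixed by its defaults:

* :func:`baseline_bias_report` — inverse-link reconstruction of the
  baseline performance / marker-bias profile from published audit
  intercepts (no simulation);
* :func:`mf1_recovery_study` — simulate recording-level macro-F1
  outcomes from a known inflated-Beta regression and check that
  refitting recovers the generating coefficients;
* :func:`disagreement_prediction_study` — simulate a multi-scorer,
  multi-model dataset with transition-localized ambiguity and predict
  epoch-level scorer disagreement from ensemble-variability features;
* :func:`ensembling_benefit_study` — measure how often the soft-voting
  ensemble of noisy probabilistic stagers beats its median member.

These drive both the test suite and the reproduction script; all
randomness flows from a single integer seed through spawned substreams.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .biasgamlss import (
    DistributionalModelSpec,
    baseline_profile,
    encode_covariates,
    fit_distributional_regression,
)
from .consensus import soft_consensus
from .ensembling import soft_vote, stage_metrics
from .hypnodata import argmax_stages
from .reference_tables import (
    ENSEMBLE_MODELS,
    MARKER_AUDIT,
    MF1_AUDIT,
    MF1_E_GENERATING_MODEL,
)
from .synthgen import (
    ModelNoiseModel,
    ScorerNoiseModel,
    default_dynamics,
    simulate_hypnogram,
    simulate_model_probs,
    simulate_performance_table,
    simulate_record,
    uniform_error_confusion,
)
from .uncertainty import (
    consensus_disagreement_labels,
    fit_disagreement_classifier,
    pairwise_disagreement,
    shannon_entropy,
    transition_proximity,
)

__all__ = [
    "baseline_bias_report",
    "default_scorer_noise",
    "default_model_noise",
    "mf1_recovery_study",
    "disagreement_prediction_study",
    "ensembling_benefit_study",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible 31-bit integer seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# Baseline reconstruction
# ---------------------------------------------------------------------------


def baseline_bias_report() -> dict:
    """Baseline (50-year-old female, AHI = PLMI = 0) profile of the four
    audited ensembles, reconstructed from published link-scale intercepts.

    Returns the across-ensemble min/max of the baseline macro-F1
    location, the boundary-inflation probability implied by the
    inflation intercepts, and the min/max baseline marker biases for
    TST, REM duration and awakenings/hour.
    """
    mf1 = [
        baseline_profile(
            "inflated-beta",
            MF1_AUDIT[m]["mu"],
            MF1_AUDIT[m]["sigma"],
            MF1_AUDIT[m]["log_nu"],
            MF1_AUDIT[m]["log_tau"],
        )
        for m in ENSEMBLE_MODELS
    ]
    out = {
        "mf1_baseline": {
            "per_model": {m: p["mu"] for m, p in zip(ENSEMBLE_MODELS, mf1)},
            "min": min(p["mu"] for p in mf1),
            "max": max(p["mu"] for p in mf1),
        },
        "mf1_zero_inflation_prob": max(
            baseline_profile(
                "inflated-beta", MF1_AUDIT["E"]["mu"],
                log_nu=MF1_AUDIT["E"]["log_nu"],
                log_tau=MF1_AUDIT["E"]["log_tau"],
            )["p0"],
            0.0,
        ),
    }
    for marker, blocks in MARKER_AUDIT.items():
        mus = [
            baseline_profile("normal", blocks[m]["mu"], blocks[m]["sigma"])["mu"]
            for m in ENSEMBLE_MODELS
        ]
        out[marker] = {"min": min(mus), "max": max(mus)}
    return out


# ---------------------------------------------------------------------------
# Inflated-Beta coefficient recovery
# ---------------------------------------------------------------------------


def mf1_recovery_study(
    seed: int,
    n: int = 2000,
    n_replicates: int = 20,
    sd_tolerance: float = 3.0,
) -> dict:
    """Simulate macro-F1 outcomes from the published generating model and
    refit; a replicate *recovers* when every mu and sigma coefficient of
    the generating model lies within ``sd_tolerance`` estimated standard
    errors of its estimate.

    The generating inflation intercepts put ~1e-10 mass on the
    boundaries, so boundary outcomes essentially never occur at this n
    and the inflation intercepts are not estimable; recovery is judged
    on the location and scale blocks. Also reports the fraction of
    replicates with a non-decreasing backfitting log-likelihood path.
    """
    gen = MF1_E_GENERATING_MODEL
    spec = DistributionalModelSpec(
        "inflated-beta", mu_terms=("gender", "ahi10"), sigma_terms=()
    )
    truth_mu = gen["mu"]
    truth_sigma = gen["sigma"]
    recovered, monotone = [], []
    fits = []
    for s in _child_seeds(seed, n_replicates):
        table = simulate_performance_table(gen, n=n, seed=s)
        cov = encode_covariates(table)
        fit = fit_distributional_regression(
            table["outcome"].to_numpy(), cov, spec
        )
        ok = True
        for name, true_val in truth_mu.items():
            est, se = fit.coef_mu[name], fit.se_mu[name]
            ok &= np.isfinite(se) and abs(est - true_val) <= sd_tolerance * se
        for name, true_val in truth_sigma.items():
            est, se = fit.coef_sigma[name], fit.se_sigma[name]
            ok &= np.isfinite(se) and abs(est - true_val) <= sd_tolerance * se
        recovered.append(bool(ok))
        path = np.asarray(fit.loglik_path)
        monotone.append(bool(np.all(np.diff(path) >= -1e-10)))
        fits.append(fit)
    return {
        "recovery_fraction": float(np.mean(recovered)),
        "loglik_monotone_fraction": float(np.mean(monotone)),
        "n_replicates": n_replicates,
        "n": n,
        "fits": fits,
    }


# ---------------------------------------------------------------------------
# Disagreement prediction
# ---------------------------------------------------------------------------


def default_scorer_noise() -> ScorerNoiseModel:
    return ScorerNoiseModel(
        base_confusion=uniform_error_confusion(0.95),
        transition_confusion=uniform_error_confusion(0.60),
        transition_window=1,
    )


def default_model_noise() -> ModelNoiseModel:
    return ModelNoiseModel(
        concentration=12.0,
        confusion=uniform_error_confusion(0.92),
        target_floor=0.05,
        transition_window=1,
        transition_concentration_scale=0.25,
        transition_confusion=uniform_error_confusion(0.60),
    )


def disagreement_prediction_study(
    seed: int,
    n_records: int = 12,
    n_epochs: int = 480,
    n_scorers: int = 5,
    n_models: int = 5,
) -> dict:
    """Leave-one-recording-out prediction of scorer disagreement from
    ensemble variability, on a simulated multi-scorer dataset whose
    scorer and model ambiguity are both localized at stage transitions.

    Returns the mean AUC for the entropy-only, distance-only and
    combined feature sets, and the mean ensemble entropy near vs away
    from transitions of the full-scorer-set consensus hypnogram.
    """
    dyn = default_dynamics(n_epochs=n_epochs)
    scorer_noise = default_scorer_noise()
    model_noise = default_model_noise()
    frames, ids = [], []
    entropy_near, entropy_far = [], []
    for i, s in enumerate(_child_seeds(seed, n_records)):
        rec, _truth = simulate_record(
            f"rec{i:02d}", dyn, scorer_noise, model_noise,
            n_scorers=n_scorers, n_models=n_models, seed=s,
        )
        models = list(rec.model_hypnodensities)
        ens = soft_vote(models)
        ent = shannon_entropy(ens)
        trace = pairwise_disagreement(models)
        labels = consensus_disagreement_labels(rec)
        frames.append(
            pd.DataFrame(
                {
                    "entropy": ent,
                    "dist_mean": trace.mean,
                    "dist_sd": trace.sd,
                    "dist_max": trace.max,
                    "label": labels,
                }
            )
        )
        ids.extend([rec.record_id] * rec.n_epochs)
        # Consensus of the full scorer set defines transition proximity.
        cons = soft_consensus(rec)
        cons_hyp = argmax_stages(cons)
        near = transition_proximity(cons_hyp, window_seconds=60.0)
        entropy_near.append(ent[near])
        entropy_far.append(ent[~near])
    data = pd.concat(frames, ignore_index=True)
    rid = np.asarray(ids)
    aucs = {
        fs: fit_disagreement_classifier(
            data, data["label"].to_numpy(), rid, feature_set=fs
        ).mean_auc
        for fs in ("entropy", "distance", "both")
    }
    return {
        "auc": aucs,
        "mean_entropy_near": float(np.concatenate(entropy_near).mean()),
        "mean_entropy_far": float(np.concatenate(entropy_far).mean()),
        "n_epochs_total": int(len(data)),
        "n_records": n_records,
    }


# ---------------------------------------------------------------------------
# Ensembling benefit
# ---------------------------------------------------------------------------


def _member_noise_models(
    rng: np.random.Generator, n_models: int
) -> list[ModelNoiseModel]:
    """Heterogeneous member stagers: each with its own accuracy and its
    own pattern of stage-specific errors."""
    noises = []
    for _ in range(n_models):
        acc = rng.uniform(0.78, 0.88)
        conf = np.zeros((5, 5))
        for row in range(5):
            off = rng.dirichlet(np.ones(4)) * (1.0 - acc)
            conf[row] = np.insert(off, row, acc)
        noises.append(ModelNoiseModel(concentration=8.0, confusion=conf))
    return noises


def ensembling_benefit_study(
    seed: int,
    n_replicates: int = 20,
    n_models: int = 10,
    n_epochs: int = 960,
) -> dict:
    """Fraction of replicates where the soft-voting ensemble's argmax
    macro-F1 meets or beats the median individual member's macro-F1."""
    dyn = default_dynamics(n_epochs=n_epochs)
    wins = []
    margins = []
    for s in _child_seeds(seed, n_replicates):
        ss = np.random.SeedSequence(s).spawn(3)
        rng = np.random.default_rng(ss[0])
        truth = simulate_hypnogram(dyn, np.random.default_rng(ss[1]))
        noises = _member_noise_models(rng, n_models)
        members = simulate_model_probs(truth, noises, n_models, seed=ss[2])
        member_mf1 = [
            stage_metrics(argmax_stages(m), truth).macro_f1 for m in members
        ]
        ens_mf1 = stage_metrics(argmax_stages(soft_vote(members)), truth).macro_f1
        med = float(np.median(member_mf1))
        wins.append(ens_mf1 >= med)
        margins.append(ens_mf1 - med)
    return {
        "benefit_fraction": float(np.mean(wins)),
        "mean_margin": float(np.mean(margins)),
        "n_replicates": n_replicates,
    }
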