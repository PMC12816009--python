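"""Soft-voting ensembles, channel majority voting, staging metrics and
paired statistical comparison of staging methods.

The ensemble of M probabilistic stagers is the per-epoch arithmetic mean
of their stage-probability rows (soft voting); across recording channels
the fusion is a per-epoch majority vote. Agreement with a reference
hypnogram is summarized by accuracy, Cohen's kappa, per-class F1 and
macro-F1 (the unweighted mean of class F1), at recording or dataset
level. Methods are compared across recordings with one-sided Wilcoxon
signed-rank tests under Bonferroni-Holm correction, with effect size
r = Z / sqrt(N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hypnodata import STAGES, Hypnodensity, Hypnogram

__all__ = [
    "MetricReport",
    "soft_vote",
    "channel_majority_vote",
    "confusion_matrix",
    "stage_metrics",
    "metrics_from_confusion",
    "aggregate",
    "paired_compare",
    "holm_adjust",
]


@dataclass(frozen=True)
class MetricReport:
    """Staging agreement summary against a reference hypnogram.

    ``class_f1`` entries are NaN for classes absent from both sequences
    (such classes are excluded from ``macro_f1``); a class present in
    exactly one sequence scores 0.
    """

    accuracy: float
    kappa: float
    macro_f1: float
    class_f1: tuple[float, ...]
    support: tuple[int, ...]
    level: str = "recording"

    def as_dict(self) -> dict[str, float]:
        d = {"accuracy": self.accuracy, "kappa": self.kappa, "macro_f1": self.macro_f1}
        for s, f in zip(STAGES, self.class_f1):
            d[f"f1_{s}"] = f
        return d


def _joint_mask(members: Sequence[Hypnogram | Hypnodensity]) -> np.ndarray:
    mask = np.ones(members[0].n_epochs, dtype=bool)
    for m in members:
        mask &= m.mask
    return mask


def soft_vote(members: Sequence[Hypnodensity]) -> Hypnodensity:
    """Element-wise average of member probability rows.

    Epochs masked in any member are masked in the output. The result is
    invariant to member order and idempotent on identical members.
    """
    members = list(members)
    if not members:
        raise ValueError("soft_vote needs at least one member")
    t0 = members[0].n_epochs
    if any(m.n_epochs != t0 or m.epoch_seconds != members[0].epoch_seconds
           for m in members):
        raise ValueError("members must share T and epoch grid")
    mask = _joint_mask(members)
    probs = np.mean([np.asarray(m.probs) for m in members], axis=0)
    probs[~mask] = 0.0
    return Hypnodensity(
        probs,
        epoch_seconds=members[0].epoch_seconds,
        source_id="+".join(m.source_id for m in members),
        mask=mask,
    )


def channel_majority_vote(
    members: Sequence[Hypnogram],
    tiebreak_probs: Sequence[Hypnodensity] | None = None,
) -> Hypnogram:
    """Per-epoch modal stage across members (e.g. channel derivations).

    Ties are broken by the summed member probabilities when matching
    hypnodensities are supplied, otherwise by the fixed stage-priority
    order W < N1 < N2 < N3 < REM. Epochs masked in any member are masked.
    """
    members = list(members)
    if not members:
        raise ValueError("majority vote needs at least one member")
    t0 = members[0].n_epochs
    if any(m.n_epochs != t0 or m.epoch_seconds != members[0].epoch_seconds
           for m in members):
        raise ValueError("members must share T and epoch grid")
    if tiebreak_probs is not None and len(tiebreak_probs) != len(members):
        raise ValueError("one hypnodensity per member required for tie-breaking")
    mask = _joint_mask(members)
    stages = np.stack([m.stages for m in members])  # (S, T)
    counts = np.zeros((t0, len(STAGES)), dtype=np.int64)
    for s in range(len(members)):
        live = stages[s] >= 0
        np.add.at(counts, (np.nonzero(live)[0], stages[s][live]), 1)
    winners = np.zeros(t0, dtype=np.int64)
    maxc = counts.max(axis=1)
    for t in range(t0):
        tied = np.nonzero(counts[t] == maxc[t])[0]
        if tied.size == 1 or tiebreak_probs is None:
            winners[t] = tied[0]  # lowest stage index among the tied
        else:
            summed = sum(np.asarray(d.probs)[t] for d in tiebreak_probs)
            winners[t] = tied[int(np.argmax(summed[tied]))]
    return Hypnogram.from_stages(
        winners,
        epoch_seconds=members[0].epoch_seconds,
        source_id="vote(" + "+".join(m.source_id for m in members) + ")",
        mask=mask,
    )


def confusion_matrix(pred: Hypnogram, ref: Hypnogram) -> np.ndarray:
    """5x5 confusion counts over the joint unmasked epochs (ref rows)."""
    if pred.n_epochs != ref.n_epochs or pred.epoch_seconds != ref.epoch_seconds:
        raise ValueError("pred and ref must share the epoch grid")
    m = pred.mask & ref.mask
    cm = np.zeros((len(STAGES), len(STAGES)), dtype=np.int64)
    np.add.at(cm, (ref.stages[m], pred.stages[m]), 1)
    return cm


def metrics_from_confusion(cm: np.ndarray, level: str = "recording") -> MetricReport:
    """Accuracy, kappa, per-class F1 and macro-F1 from a confusion matrix."""
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    if n == 0:
        raise ValueError("empty joint mask: no epochs to score")
    acc = np.trace(cm) / n
    ref_marg = cm.sum(axis=1) / n
    pred_marg = cm.sum(axis=0) / n
    pe = float(ref_marg @ pred_marg)
    # kappa := 1 by convention when both sequences are one identical
    # constant class (pe == 1 and perfect agreement).
    kappa = 1.0 if pe >= 1.0 else (acc - pe) / (1.0 - pe)
    class_f1 = []
    for c in range(len(STAGES)):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        if tp + fp + fn == 0:
            class_f1.append(np.nan)  # class absent everywhere: excluded from MF1
        else:
            class_f1.append(2 * tp / (2 * tp + fp + fn))
    defined = [f for f in class_f1 if not math.isnan(f)]
    mf1 = float(np.mean(defined)) if defined else np.nan
    return MetricReport(
        accuracy=float(acc),
        kappa=float(kappa),
        macro_f1=mf1,
        class_f1=tuple(class_f1),
        support=tuple(int(x) for x in cm.sum(axis=1)),
        level=level,
    )


def stage_metrics(pred: Hypnogram, ref: Hypnogram) -> MetricReport:
    """Score a predicted hypnogram against a reference on their joint mask."""
    return metrics_from_confusion(confusion_matrix(pred, ref))


def aggregate(
    pairs: Iterable[tuple[Hypnogram, Hypnogram]],
    level: str = "recording",
) -> pd.DataFrame:
    """Aggregate metrics over recordings.

    ``recording`` level: each recording is scored separately; the table
    holds the per-recording rows plus mean and SD rows (recordings
    weighted equally). ``dataset`` level: confusion matrices are pooled
    over all epochs of all recordings and scored once.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one recording")
    if level == "recording":
        rows = [stage_metrics(p, r).as_dict() for p, r in pairs]
        df = pd.DataFrame(rows)
        summary = pd.DataFrame(
            [df.mean(axis=0), df.std(axis=0, ddof=0)], index=["mean", "sd"]
        )
        return pd.concat([df, summary])
    if level == "dataset":
        cm = sum(confusion_matrix(p, r) for p, r in pairs)
        rep = metrics_from_confusion(cm, level="dataset")
        return pd.DataFrame([rep.as_dict()], index=["dataset"])
    raise ValueError("level must be 'recording' or 'dataset'")


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values."""
    return multipletests(np.asarray(pvalues, float), method="holm")[1]


def _signed_rank_z(diff: np.ndarray) -> float:
    """Normal-approximation Z of the signed-rank statistic (tie-corrected),
    signed so that positive Z favors the alternative 'greater'."""
    d = diff[diff != 0]
    n = d.size
    if n == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        return 0.0
    return float((w_plus - mu) / math.sqrt(var))


def _exact_tail_with_ties(d: np.ndarray, alternative: str) -> float:
    """One-sided signed-rank p by full sign-flip enumeration (midranks)."""
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = ranks.size
    count = 0
    for bits in range(2**n):
        w = sum(ranks[i] for i in range(n) if bits >> i & 1)
        if alternative == "greater":
            count += w >= w_obs - 1e-9
        else:
            count += w <= w_obs + 1e-9
    return count / 2**n


def paired_compare(
    metric_matrix: pd.DataFrame,
    reference_method: str,
    alternative: str = "greater",
    exact_max_n: int = 25,
) -> pd.DataFrame:
    """Compare each method against a reference across recordings.

    ``metric_matrix`` is recordings x methods with no missing cells. For
    every non-reference column the one-sided Wilcoxon signed-rank test of
    ``method - reference`` is computed (exact null for n <= ``exact_max_n``
    without ties, normal approximation with continuity correction above),
    Holm-adjusted over the family of comparisons in this call, with
    effect size r = Z / sqrt(N) where N counts non-zero differences.
    Degenerate comparisons (all differences zero) get p = 1, r = 0 and
    are flagged.
    """
    if reference_method not in metric_matrix.columns:
        raise KeyError(f"reference method {reference_method!r} not in matrix")
    if metric_matrix.isna().any().any():
        raise ValueError("metric matrix must have no missing cells")
    if len(metric_matrix) < 6:
        raise ValueError("need at least 6 recordings for a paired comparison")
    ref = metric_matrix[reference_method].to_numpy(float)
    rows = []
    for method in metric_matrix.columns:
        if method == reference_method:
            continue
        diff = metric_matrix[method].to_numpy(float) - ref
        nz = int(np.count_nonzero(diff))
        degenerate = nz == 0
        if degenerate:
            p, z = 1.0, 0.0
        else:
            d = diff[diff != 0]
            has_ties = np.unique(np.abs(d)).size < d.size
            if d.size <= exact_max_n and not has_ties:
                res = stats.wilcoxon(d, alternative=alternative, method="exact")
                p = float(res.pvalue)
            elif d.size <= 15:  # tied ranks: exact sign-flip null by enumeration
                p = _exact_tail_with_ties(d, alternative)
            else:
                res = stats.wilcoxon(
                    d, alternative=alternative, method="approx", correction=True
                )
                p = float(res.pvalue)
            z = _signed_rank_z(diff)
            if alternative == "less":
                z = -z
        rows.append(
            {
                "method": method,
                "n_pairs": nz,
                "Z": z,
                "p_raw": p,
                "r": z / math.sqrt(nz) if nz else 0.0,
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows).set_index("method")
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out[["n_pairs", "Z", "p_raw", "p_holm", "r", "degenerate"]]
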