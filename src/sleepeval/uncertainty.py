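"""Ensemble-variability metrics and prediction of scorer disagreement.

Two complementary per-epoch uncertainty signals are computed from an
ensemble of probabilistic stagers: the Shannon entropy (natural log) of
the soft-voting output, and the set of pairwise cosine distances between
the members' probability rows, summarized by mean, standard deviation
and maximum (optionally compressed to a first principal component).
Epochs are stratified by proximity to stage transitions of a consensus
hypnogram, and epoch-level human disagreement (scorer set not unanimous)
is predicted from the variability features with a logistic classifier
under leave-one-recording-out cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .consensus import soft_consensus
from .hypnodata import Hypnodensity, Hypnogram, MultiScorerRecord

__all__ = [
    "UncertaintyTrace",
    "DisagreementModel",
    "shannon_entropy",
    "pairwise_disagreement",
    "disagreement_pc1",
    "transition_proximity",
    "consensus_disagreement_labels",
    "fit_disagreement_classifier",
]

MAX_ENTROPY = float(np.log(5))


@dataclass(frozen=True)
class UncertaintyTrace:
    """Per-epoch pairwise cosine distances and their summaries.

    ``distances`` is T x M(M-1)/2; masked epochs carry NaN rows.
    """

    distances: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    max: np.ndarray
    mask: np.ndarray

    def summaries(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "sd": self.sd, "max": self.max}
        )


@dataclass(frozen=True)
class DisagreementModel:
    """Leave-one-recording-out logistic disagreement classifier.

    Coefficients are from a final fit on all pooled (standardized)
    epochs; fold AUCs are computed on each held-out recording with
    standardization parameters estimated on the training folds only.
    """

    feature_names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    fold_aucs: pd.Series
    skipped_folds: tuple[str, ...]
    mean_auc: float


def shannon_entropy(d: Hypnodensity) -> np.ndarray:
    """Per-epoch Shannon entropy in nats, with 0*log(0) := 0.

    Bounded by log(5) ~ 1.6094 (uniform row); masked epochs yield NaN.
    """
    p = np.asarray(d.probs, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1)
    h[~d.mask] = np.nan
    return h


def pairwise_disagreement(models: list[Hypnodensity]) -> UncertaintyTrace:
    """All unique-pair cosine distances per epoch, with summaries.

    For M members each epoch yields M(M-1)/2 distances 1 - cos(p_m, p_n);
    summaries are their mean, population SD and maximum. Invariant to
    member order.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 ensemble members")
    t0 = models[0].n_epochs
    if any(m.n_epochs != t0 or m.epoch_seconds != models[0].epoch_seconds
           for m in models):
        raise ValueError("members must share T and epoch grid")
    mask = np.ones(t0, dtype=bool)
    for m in models:
        mask &= m.mask
    mats = [np.asarray(m.probs) for m in models]
    norms = [np.linalg.norm(p, axis=1) for p in mats]
    cols = []
    for i, j in combinations(range(len(models)), 2):
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = (mats[i] * mats[j]).sum(axis=1) / (norms[i] * norms[j])
        cols.append(1.0 - sim)
    dist = np.column_stack(cols)
    dist[~mask] = np.nan
    return UncertaintyTrace(
        distances=dist,
        mean=dist.mean(axis=1),
        sd=dist.std(axis=1, ddof=0),
        max=dist.max(axis=1) if dist.shape[1] else dist.mean(axis=1),
        mask=mask,
    )


def disagreement_pc1(summaries: pd.DataFrame | np.ndarray) -> np.ndarray:
    """First principal component of the standardized distance summaries.

    Columns (mean, SD, max) are standardized to zero mean / unit
    variance; zero-variance columns are dropped with a warning. The PC1
    score sign is oriented to correlate positively with the first
    (mean-distance) column. A fully degenerate table returns all zeros.
    """
    x = np.asarray(summaries, float)
    if x.ndim != 2:
        raise ValueError("summaries must be a 2-D table")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 epochs")
    if not np.all(np.isfinite(x)):
        raise ValueError("summaries must be finite")
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn("dropping zero-variance summary column(s)", stacklevel=2)
    if not keep.any():
        return np.zeros(x.shape[0])
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    scores = PCA(n_components=1).fit_transform(z)[:, 0]
    anchor = z[:, 0]
    corr = np.corrcoef(scores, anchor)[0, 1] if scores.std() > 0 else 0.0
    if corr < 0:
        scores = -scores
    return scores


def transition_proximity(
    consensus: Hypnogram, window_seconds: float = 60.0
) -> np.ndarray:
    """Flag epochs lying near a stage transition of a consensus hypnogram.

    A transition is a stage change between consecutive unmasked epochs;
    its boundary is the shared epoch edge. An epoch is *near* when the
    time gap between its interval and the nearest boundary is strictly
    below ``window_seconds``; the two epochs touching a boundary (gap 0)
    are always flagged. At 30-s epochs the default 60-s window flags the
    two epochs on each side of every boundary.
    """
    stages = consensus.stages
    mask = consensus.mask
    eps = consensus.epoch_seconds
    t = consensus.n_epochs
    near = np.zeros(t, dtype=bool)
    prev = None  # index of previous unmasked epoch
    boundaries = []  # boundary between epochs b-1 and b stored as b
    for i in range(t):
        if not mask[i]:
            continue
        if prev is not None and stages[i] != stages[prev] and prev == i - 1:
            boundaries.append(i)
        prev = i
    for b in boundaries:
        for i in range(t):
            gap = (b - 1 - i) * eps if i < b else (i - b) * eps
            if gap == 0 or gap < window_seconds:
                near[i] = True
    near[~mask] = False
    return near


def consensus_disagreement_labels(
    record: MultiScorerRecord, scorer_set: tuple[str, ...] | None = None
) -> np.ndarray:
    """True where the scorer set is not unanimous at an epoch.

    Equivalent to the maximum of the soft-consensus row being below 1.
    Epochs where the whole set is masked are False (no evidence).
    """
    if len(record.scorer_hypnograms) < 2:
        raise ValueError("need at least 2 scorers")
    sc = soft_consensus(record, scorer_set)
    labels = np.zeros(record.n_epochs, dtype=bool)
    live = sc.mask
    labels[live] = np.asarray(sc.probs)[live].max(axis=1) < 1.0 - 1e-12
    return labels


def _standardize(train: np.ndarray, apply: np.ndarray) -> np.ndarray:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (apply - mu) / sd


def _logistic_fit(x: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """Unpenalized ML logistic fit; separable data falls back to a tiny
    ridge with a warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(C=np.inf, max_iter=2000, tol=1e-8)
            clf.fit(x, y)
            return clf
        except ConvergenceWarning:
            warnings.simplefilter("default", ConvergenceWarning)
            warnings.warn(
                "logistic fit did not converge (separable data?); "
                "falling back to a tiny ridge",
                stacklevel=3,
            )
            clf = LogisticRegression(C=1e6, max_iter=2000, tol=1e-8)
            clf.fit(x, y)
            return clf


_FEATURE_SETS = {
    "entropy": ("entropy",),
    "distance": ("dist_mean", "dist_sd", "dist_max"),
    "both": ("entropy", "dist_mean", "dist_sd", "dist_max"),
}


def fit_disagreement_classifier(
    features: pd.DataFrame,
    labels: np.ndarray,
    recording_ids: np.ndarray,
    feature_set: str = "both",
) -> DisagreementModel:
    """Predict epoch-level scorer disagreement from ensemble variability.

    ``features`` must provide columns ``entropy``, ``dist_mean``,
    ``dist_sd``, ``dist_max`` (the ``feature_set`` argument selects the
    entropy group, the distance-summary group, or both). One logistic
    regression per leave-one-recording-out fold, features standardized
    on the training folds only; folds whose held-out recording has a
    single label class are skipped and reported. The headline number is
    the unweighted mean AUC over valid folds.
    """
    if feature_set not in _FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {sorted(_FEATURE_SETS)}")
    cols = list(_FEATURE_SETS[feature_set])
    x = features[cols].to_numpy(float)
    y = np.asarray(labels, bool).astype(int)
    rid = np.asarray(recording_ids)
    if np.unique(rid).size < 2:
        raise ValueError("need at least 2 recordings for cross-validation")
    if np.unique(y).size < 2:
        raise ValueError("labels are constant overall")
    aucs: dict[str, float] = {}
    skipped: list[str] = []
    for rec in np.unique(rid):
        held = rid == rec
        if np.unique(y[held]).size < 2:
            skipped.append(str(rec))
            continue
        xtr = x[~held]
        clf = _logistic_fit(_standardize(xtr, xtr), y[~held])
        scores = clf.decision_function(_standardize(xtr, x[held]))
        aucs[str(rec)] = float(roc_auc_score(y[held], scores))
    if not aucs:
        raise ValueError("every fold had single-class held-out labels")
    final = _logistic_fit(_standardize(x, x), y)
    fold_series = pd.Series(aucs).sort_index()
    return DisagreementModel(
        feature_names=tuple(cols),
        coefficients=final.coef_[0].copy(),
        intercept=float(final.intercept_[0]),
        fold_aucs=fold_series,
        skipped_folds=tuple(skipped),
        mean_auc=float(fold_series.mean()),
    )
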