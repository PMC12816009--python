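"""Multi-scorer probabilistic consensus and hypnodensity similarity.

With S human scorers labelling the same recording, each scorer s can be
evaluated against the *probabilistic consensus* of the others: at every
epoch the one-hot votes of the other scorers are summed and divided by
the row maximum, so the most frequent stage(s) score 1. The mean of the
consensus value at the scorer's own label is the *soft-agreement*, a
[0, 1] reliability score. Reliability rankings drive two derived
objects: the *consensus hypnogram* (per-epoch majority vote with ties
resolved by the most reliable scorer) and the selected scorer set used
to evaluate automatic models. The *soft-consensus* is the per-epoch
empirical label distribution over a scorer set, and two hypnodensities
are compared by their averaged per-epoch cosine similarity (ACS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypnodata import STAGES, Hypnodensity, Hypnogram, MultiScorerRecord, to_onehot

__all__ = [
    "ConsensusProfile",
    "ScorerReliability",
    "probabilistic_consensus",
    "soft_agreement",
    "rank_scorers",
    "consensus_hypnogram",
    "soft_consensus",
    "cosine_similarity",
    "acs",
]


@dataclass(frozen=True)
class ConsensusProfile:
    """Normalized per-epoch vote profile of a scorer set.

    Each unmasked row has maximum 1; rows where every contributing
    scorer is masked are masked.
    """

    z: np.ndarray
    mask: np.ndarray
    excluded_scorer: str | None = None


@dataclass(frozen=True)
class ScorerReliability:
    """Soft-agreement reliability summaries over a dataset.

    ``per_recording``: recordings x scorers soft-agreement table;
    ``dataset``: unweighted mean per scorer; ``ranking``: scorer ids by
    decreasing dataset reliability (ties broken by id order);
    ``selected``: the top-k most reliable scorers.
    """

    per_recording: pd.DataFrame
    dataset: pd.Series
    ranking: tuple[str, ...]
    selected: tuple[str, ...]


def _vote_counts(
    record: MultiScorerRecord, exclude: str | None
) -> tuple[np.ndarray, np.ndarray]:
    """Summed one-hot votes of the non-excluded scorers and the count of
    contributing (unmasked) scorers per epoch."""
    scorers = [h for h in record.scorer_hypnograms if h.source_id != exclude]
    if exclude is not None and len(scorers) == len(record.scorer_hypnograms):
        raise KeyError(f"no scorer {exclude!r} in record {record.record_id!r}")
    if not scorers:
        raise ValueError("all scorers excluded")
    counts = np.zeros((record.n_epochs, len(STAGES)))
    contributing = np.zeros(record.n_epochs)
    for h in scorers:
        oh = to_onehot(h)
        counts += np.asarray(oh.probs)
        contributing += h.mask
    return counts, contributing


def probabilistic_consensus(
    record: MultiScorerRecord, exclude: str | None = None
) -> ConsensusProfile:
    """Per-epoch vote profile of the scorers other than ``exclude``,
    normalized by the row maximum (modal stages score 1; ties leave
    several stages at 1). A scorer masked at an epoch simply drops out of
    that epoch's sum; epochs with no contributing scorer are masked."""
    if exclude is not None and len(record.scorer_hypnograms) < 2:
        raise ValueError("excluding a scorer requires at least 2 scorers")
    counts, contributing = _vote_counts(record, exclude)
    mask = contributing > 0
    z = np.zeros_like(counts)
    row_max = counts[mask].max(axis=1)
    z[mask] = counts[mask] / row_max[:, None]
    return ConsensusProfile(z=z, mask=mask, excluded_scorer=exclude)


def soft_agreement(record: MultiScorerRecord, scorer_id: str) -> float:
    """Mean consensus-profile value at the scorer's own labels.

    1 means the scorer always sits on the (normalized) majority of the
    others; 0 means it always stands alone. Computed over the epochs
    where both the scorer and the consensus are unmasked.
    """
    if len(record.scorer_hypnograms) < 2:
        raise ValueError("soft-agreement requires at least 2 scorers")
    scorer = record.scorer(scorer_id)
    profile = probabilistic_consensus(record, exclude=scorer_id)
    live = scorer.mask & profile.mask
    if not live.any():
        raise ValueError("no unmasked epochs shared with the consensus")
    idx = scorer.stages[live]
    return float(profile.z[live, idx].mean())


def rank_scorers(
    records: list[MultiScorerRecord], top_k: int = 4
) -> ScorerReliability:
    """Rank scorers by soft-agreement, per recording and dataset-wide.

    The dataset reliability of a scorer is the unweighted mean of its
    per-recording soft-agreements; scorers absent from some recordings
    are excluded from the dataset ranking. ``selected`` keeps the
    ``top_k`` most reliable scorers (the set used when evaluating
    automatic models against the human consensus). Ties break by scorer
    id lexicographic order.
    """
    if not records:
        raise ValueError("need at least one record")
    per_rec = pd.DataFrame(
        {
            rec.record_id: {
                sid: soft_agreement(rec, sid) for sid in rec.scorer_ids
            }
            for rec in records
        }
    ).T
    complete = [c for c in per_rec.columns if per_rec[c].notna().all()]
    dropped = sorted(set(per_rec.columns) - set(complete))
    if dropped:
        import warnings

        warnings.warn(
            f"scorer(s) {dropped} absent from some recordings; "
            "excluded from the dataset ranking",
            stacklevel=2,
        )
    dataset = per_rec[complete].mean(axis=0)
    ranking = tuple(
        sorted(dataset.index, key=lambda sid: (-dataset[sid], sid))
    )
    return ScorerReliability(
        per_recording=per_rec,
        dataset=dataset,
        ranking=ranking,
        selected=ranking[: min(top_k, len(ranking))],
    )


def _recording_reliability_order(
    record: MultiScorerRecord, scorer_ids: tuple[str, ...]
) -> list[str]:
    sa = {sid: soft_agreement(record, sid) for sid in scorer_ids}
    return sorted(scorer_ids, key=lambda sid: (-sa[sid], sid))


def consensus_hypnogram(
    record: MultiScorerRecord,
    for_scorer: str | None = None,
    scorer_set: tuple[str, ...] | None = None,
) -> Hypnogram:
    """Per-epoch majority vote of a scorer set, ties resolved by the most
    reliable scorer of this recording.

    When evaluating a human scorer, pass ``for_scorer`` to exclude them
    and vote among the remaining scorers. When evaluating an automatic
    model, pass ``scorer_set`` (typically the dataset-wide top-4 most
    reliable scorers). Reliability for tie-breaking is this recording's
    soft-agreement ranking among the voting scorers.
    """
    if for_scorer is not None and scorer_set is not None:
        raise ValueError("pass either for_scorer or scorer_set, not both")
    if for_scorer is not None:
        voters = tuple(
            sid for sid in record.scorer_ids if sid != for_scorer
        )
        if len(voters) == len(record.scorer_ids):
            raise KeyError(f"no scorer {for_scorer!r}")
    elif scorer_set is not None:
        voters = tuple(scorer_set)
    else:
        voters = record.scorer_ids
    if not voters:
        raise ValueError("empty scorer set")
    sub = MultiScorerRecord(
        record.record_id,
        tuple(record.scorer(sid) for sid in voters),
    )
    counts, contributing = _vote_counts(sub, exclude=None)
    mask = contributing > 0
    # Tie-break order: this recording's reliability ranking among the
    # voters (needs >= 2 voters to be defined; with one voter no ties).
    if len(voters) >= 2:
        order = _recording_reliability_order(sub, voters)
    else:
        order = list(voters)
    stage_by_scorer = {sid: record.scorer(sid).stages for sid in voters}
    winners = np.zeros(record.n_epochs, dtype=np.int64)
    maxc = counts.max(axis=1)
    for t in np.nonzero(mask)[0]:
        tied = np.nonzero(counts[t] == maxc[t])[0]
        if tied.size == 1:
            winners[t] = tied[0]
            continue
        for sid in order:
            s = stage_by_scorer[sid][t]
            if s in tied:
                winners[t] = s
                break
        else:  # most reliable scorers all masked here: lowest tied stage
            winners[t] = tied[0]
    return Hypnogram.from_stages(
        winners,
        epoch_seconds=record.epoch_seconds,
        source_id=f"consensus({record.record_id})",
        mask=mask,
    )


def soft_consensus(
    record: MultiScorerRecord, scorer_set: tuple[str, ...] | None = None
) -> Hypnodensity:
    """Per-epoch empirical label distribution over a scorer set.

    Equal-weight mean of the scorers' one-hot encodings; rows sum to 1.
    Epochs where every scorer in the set is masked are masked.
    """
    voters = tuple(scorer_set) if scorer_set is not None else record.scorer_ids
    if not voters:
        raise ValueError("empty scorer set")
    sub = MultiScorerRecord(record.record_id, tuple(record.scorer(s) for s in voters))
    counts, contributing = _vote_counts(sub, exclude=None)
    mask = contributing > 0
    probs = np.zeros_like(counts)
    probs[mask] = counts[mask] / contributing[mask, None]
    return Hypnodensity(
        probs,
        epoch_seconds=record.epoch_seconds,
        source_id=f"soft-consensus({record.record_id})",
        mask=mask,
    )


def cosine_similarity(p: np.ndarray, q: np.ndarray) -> float:
    """Cosine of two stage-probability vectors; in (0, 1] for valid rows."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    np_, nq = np.linalg.norm(p), np.linalg.norm(q)
    if np_ == 0 or nq == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(p @ q / (np_ * nq))


def acs(d1: Hypnodensity, d2: Hypnodensity) -> float:
    """Averaged cosine similarity between two hypnodensities.

    Mean of the per-epoch cosine similarities over the epochs unmasked
    in both inputs; for one-hot inputs this equals plain epoch accuracy.
    """
    if d1.n_epochs != d2.n_epochs or d1.epoch_seconds != d2.epoch_seconds:
        raise ValueError("hypnodensities must share the epoch grid")
    live = d1.mask & d2.mask
    if not live.any():
        raise ValueError("no shared unmasked epochs")
    a = np.asarray(d1.probs)[live]
    b = np.asarray(d2.probs)[live]
    sims = (a * b).sum(axis=1) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    )
    return float(sims.mean())
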