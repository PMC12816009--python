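"""Probabilistic consensus, soft-agreement, reliability and ACS."""

import numpy as np
import pytest

from sleepeval.consensus import (
    acs,
    consensus_hypnogram,
    cosine_similarity,
    probabilistic_consensus,
    rank_scorers,
    soft_agreement,
    soft_consensus,
)
from sleepeval.ensembling import soft_vote
from sleepeval.hypnodata import Hypnogram, MultiScorerRecord, to_onehot
from tests.conftest import random_hypnodensity, random_hypnogram


def record_from_labels(*label_rows: str) -> MultiScorerRecord:
    """Build a record from per-scorer space-separated label strings."""
    scorers = tuple(
        Hypnogram(tuple(row.split()), source_id=f"s{i}")
        for i, row in enumerate(label_rows)
    )
    return MultiScorerRecord("rec", scorers)


class TestProbabilisticConsensus:
    def test_mixed_votes_normalized_by_row_max(self):
        rec = record_from_labels("N3", "N2", "N2", "N1", "W")
        prof = probabilistic_consensus(rec, exclude="s0")
        assert np.allclose(prof.z[0], [0.5, 0.5, 1.0, 0.0, 0.0])

    def test_unanimous_others(self):
        rec = record_from_labels("W", "N3", "N3", "N3")
        prof = probabilistic_consensus(rec, exclude="s0")
        assert np.allclose(prof.z[0], [0, 0, 0, 1, 0])

    def test_two_way_tie_leaves_both_at_one(self):
        rec = record_from_labels("N2", "W", "REM")
        prof = probabilistic_consensus(rec, exclude="s0")
        assert np.allclose(prof.z[0], [1, 0, 0, 0, 1])

    def test_masked_scorer_drops_out_of_epoch(self):
        rec = record_from_labels("N2 N2", "MOVEMENT N2", "N1 N1")
        prof = probabilistic_consensus(rec, exclude=None)
        # epoch 0: only s0 (N2) and s2 (N1) vote
        assert np.allclose(prof.z[0], [0, 1, 1, 0, 0])

    def test_all_scorers_excluded_errors(self):
        rec = record_from_labels("W")
        with pytest.raises(ValueError):
            probabilistic_consensus(rec, exclude="s0")


class TestSoftAgreement:
    def test_agreeing_with_unanimous_others_is_one(self):
        rec = record_from_labels("N2 W", "N2 W", "N2 W")
        assert soft_agreement(rec, "s0") == 1.0

    def test_always_alone_is_zero(self):
        rec = record_from_labels("REM REM", "N2 W", "N2 W")
        assert soft_agreement(rec, "s0") == 0.0

    def test_matches_enumeration_oracle(self):
        rows = ["N2 N1 W REM", "N2 N2 W N3", "N1 N2 W REM"]
        rec = record_from_labels(*rows)
        idx = {"W": 0, "N1": 1, "N2": 2, "N3": 3, "REM": 4}
        for s, row in enumerate(rows):
            labels = row.split()
            total = 0.0
            for t, lab in enumerate(labels):
                counts = [0.0] * 5
                for s2, row2 in enumerate(rows):
                    if s2 != s:
                        counts[idx[row2.split()[t]]] += 1
                total += counts[idx[lab]] / max(counts)
            expected = total / len(labels)
            assert soft_agreement(rec, f"s{s}") == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_other_scorer_ordering(self, rng):
        scorers = [random_hypnogram(rng, 30, source_id=f"s{i}") for i in range(4)]
        a = soft_agreement(MultiScorerRecord("r", tuple(scorers)), "s0")
        reordered = (scorers[0], scorers[3], scorers[1], scorers[2])
        b = soft_agreement(MultiScorerRecord("r", reordered), "s0")
        assert a == pytest.approx(b, abs=1e-15)


class TestRankScorers:
    def test_identical_scorers_tie_broken_by_id(self, rng):
        base = random_hypnogram(rng, 40)
        scorers = tuple(base.with_source(f"s{i}") for i in range(5))
        rel = rank_scorers([MultiScorerRecord("r", scorers)])
        assert np.allclose(rel.dataset.to_numpy(), 1.0)
        assert rel.ranking == ("s0", "s1", "s2", "s3", "s4")

    def test_incoherent_scorer_ranked_last(self, rng):
        base = random_hypnogram(rng, 200)
        permuted = Hypnogram(
            tuple(np.roll(np.array(base.labels, dtype=object), 7)),
            source_id="odd",
        )
        scorers = tuple(base.with_source(f"s{i}") for i in range(4)) + (permuted,)
        rel = rank_scorers([MultiScorerRecord("r", scorers)])
        assert rel.ranking[-1] == "odd"

    def test_top_four_selected_from_five(self, rng):
        scorers = tuple(
            random_hypnogram(rng, 50, source_id=f"s{i}") for i in range(5)
        )
        rel = rank_scorers([MultiScorerRecord("r", scorers)])
        assert len(rel.selected) == 4


class TestConsensusHypnogram:
    def test_majority_wins(self):
        rec = record_from_labels("N2", "N2", "W")
        assert consensus_hypnogram(rec).labels == ("N2",)

    def test_tie_resolved_by_most_reliable_scorer(self):
        # s0 and s1 agree on later epochs, making one of them most
        # reliable; the tied first epoch must follow that scorer's vote.
        rec = record_from_labels("W N2 N2 N2", "N2 N2 N2 N2", "N1 W W W", "REM N2 N2 N2")
        rel = {sid: soft_agreement(rec, sid) for sid in rec.scorer_ids}
        best = max(sorted(rel), key=lambda s: rel[s])
        got = consensus_hypnogram(rec).labels[0]
        assert got == rec.scorer(best).labels[0]

    def test_equals_plain_majority_without_ties(self, rng):
        scorers = tuple(
            random_hypnogram(rng, 300, source_id=f"s{i}") for i in range(5)
        )
        rec = MultiScorerRecord("r", scorers)
        cons = consensus_hypnogram(rec).stages
        stages = np.stack([h.stages for h in scorers])
        for t in range(300):
            counts = np.bincount(stages[:, t], minlength=5)
            if (counts == counts.max()).sum() == 1:
                assert cons[t] == counts.argmax()

    def test_matches_brute_force_vote_and_tie_oracle(self, rng):
        scorers = tuple(
            random_hypnogram(rng, 2000, source_id=f"s{i}") for i in range(4)
        )
        rec = MultiScorerRecord("r", scorers)
        rel = {sid: soft_agreement(rec, sid) for sid in rec.scorer_ids}
        order = sorted(rec.scorer_ids, key=lambda s: (-rel[s], s))
        got = consensus_hypnogram(rec).stages
        stages = {sid: rec.scorer(sid).stages for sid in rec.scorer_ids}
        for t in range(2000):
            counts = np.bincount(
                [stages[s][t] for s in rec.scorer_ids], minlength=5
            )
            tied = np.flatnonzero(counts == counts.max())
            if tied.size == 1:
                expected = tied[0]
            else:
                expected = next(
                    stages[s][t] for s in order if stages[s][t] in tied
                )
            assert got[t] == expected


class TestSoftConsensus:
    def test_unanimous(self):
        rec = record_from_labels("REM", "REM", "REM", "REM")
        assert np.allclose(soft_consensus(rec).probs[0], [0, 0, 0, 0, 1])

    def test_split_two_one_one(self):
        rec = record_from_labels("N2", "N2", "N1", "N3")
        assert np.allclose(soft_consensus(rec).probs[0], [0, 0.25, 0.5, 0.25, 0])

    def test_equals_soft_vote_of_onehots(self, rng):
        scorers = tuple(
            random_hypnogram(rng, 60, source_id=f"s{i}") for i in range(4)
        )
        rec = MultiScorerRecord("r", scorers)
        via_vote = soft_vote([to_onehot(h) for h in scorers])
        assert np.allclose(soft_consensus(rec).probs, via_vote.probs)


class TestCosineAndACS:
    def test_identical_rows(self):
        assert cosine_similarity([0.2, 0.8, 0, 0, 0], [0.2, 0.8, 0, 0, 0]) == (
            pytest.approx(1.0)
        )

    def test_disjoint_onehots(self):
        assert cosine_similarity([1, 0, 0, 0, 0], [0, 1, 0, 0, 0]) == 0.0

    def test_hand_value(self):
        got = cosine_similarity([0.5, 0.5, 0, 0, 0], [1, 0, 0, 0, 0])
        assert got == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0, 0, 0, 0], [1, 0, 0, 0, 0])

    def test_acs_identical_is_one(self, rng):
        d = random_hypnodensity(rng, 40)
        assert acs(d, d) == pytest.approx(1.0)

    def test_acs_disjoint_onehots_is_zero(self):
        a = to_onehot(Hypnogram(("W", "N1", "N2")))
        b = to_onehot(Hypnogram(("N1", "N2", "N3")))
        assert acs(a, b) == 0.0

    def test_acs_matches_brute_force_mean(self, rng):
        d1 = random_hypnodensity(rng, 300)
        d2 = random_hypnodensity(rng, 300)
        total = 0.0
        for t in range(300):
            p, q = d1.probs[t], d2.probs[t]
            total += p @ q / (np.linalg.norm(p) * np.linalg.norm(q))
        assert acs(d1, d2) == pytest.approx(total / 300, abs=1e-12)
        assert acs(d1, d2) == pytest.approx(acs(d2, d1), abs=1e-15)

    def test_acs_of_onehots_is_accuracy(self, rng):
        h1 = random_hypnogram(rng, 200)
        h2 = random_hypnogram(rng, 200)
        accuracy = float(np.mean(h1.stages == h2.stages))
        assert acs(to_onehot(h1), to_onehot(h2)) == pytest.approx(accuracy)
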