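"""Soft voting, majority voting, staging metrics and paired tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, f1_score

from sleepeval.ensembling import (
    aggregate,
    channel_majority_vote,
    confusion_matrix,
    holm_adjust,
    metrics_from_confusion,
    paired_compare,
    soft_vote,
    stage_metrics,
)
from sleepeval.hypnodata import Hypnodensity, Hypnogram
from tests.conftest import random_hypnodensity, random_hypnogram


class TestSoftVote:
    def test_two_member_mean(self):
        a = Hypnodensity(np.array([[1.0, 0, 0, 0, 0]]))
        b = Hypnodensity(np.array([[0, 1.0, 0, 0, 0]]))
        assert np.allclose(soft_vote([a, b]).probs[0], [0.5, 0.5, 0, 0, 0])

    def test_idempotent_on_identical_members(self, rng):
        d = random_hypnodensity(rng, 50)
        ens = soft_vote([d, d, d])
        assert np.allclose(ens.probs, d.probs)

    def test_matches_brute_force_cell_mean(self, rng):
        members = [random_hypnodensity(rng, 200) for _ in range(5)]
        ens = soft_vote(members)
        expected = np.zeros((200, 5))
        for t in range(200):
            for c in range(5):
                expected[t, c] = sum(m.probs[t, c] for m in members) / 5
        assert np.max(np.abs(ens.probs - expected)) < 1e-12

    def test_permutation_invariant(self, rng):
        members = [random_hypnodensity(rng, 30) for _ in range(4)]
        a = soft_vote(members).probs
        b = soft_vote(members[::-1]).probs
        assert np.allclose(a, b)

    def test_empty_member_list_errors(self):
        with pytest.raises(ValueError):
            soft_vote([])


class TestMajorityVote:
    def test_modal_stage_wins(self):
        members = [Hypnogram((s,)) for s in ("N2", "N2", "W")]
        for i, m in enumerate(members):
            members[i] = m.with_source(f"c{i}")
        assert channel_majority_vote(members).labels == ("N2",)

    def test_tie_goes_to_stage_priority_order(self):
        members = [
            Hypnogram(("N2",), source_id="a"),
            Hypnogram(("W",), source_id="b"),
        ]
        assert channel_majority_vote(members).labels == ("W",)

    def test_tie_broken_by_summed_probabilities(self):
        members = [
            Hypnogram(("N2",), source_id="a"),
            Hypnogram(("W",), source_id="b"),
        ]
        probs = [
            Hypnodensity(np.array([[0.1, 0.0, 0.9, 0.0, 0.0]])),
            Hypnodensity(np.array([[0.55, 0.0, 0.45, 0.0, 0.0]])),
        ]
        got = channel_majority_vote(members, tiebreak_probs=probs)
        assert got.labels == ("N2",)  # summed N2 mass 1.35 > W mass 0.65

    def test_matches_brute_force_counting(self, rng):
        members = [random_hypnogram(rng, 10_000, source_id=f"c{i}") for i in range(4)]
        got = channel_majority_vote(members).stages
        stages = np.stack([m.stages for m in members])
        for t in range(10_000):
            counts = [0] * 5
            for s in stages[:, t]:
                counts[s] += 1
            best = max(counts)
            expected = counts.index(best)  # lowest index among ties
            assert got[t] == expected


class TestStageMetrics:
    def test_perfect_prediction(self):
        h = Hypnogram(("W", "N1", "N2", "N3", "REM"))
        rep = stage_metrics(h, h)
        assert rep.accuracy == 1.0
        assert rep.kappa == 1.0
        assert rep.macro_f1 == 1.0

    def test_disjoint_constant_sequences_give_zero_kappa(self):
        pred = Hypnogram(("W",) * 10)
        ref = Hypnogram(("N2",) * 10)
        rep = stage_metrics(pred, ref)
        assert rep.accuracy == 0.0
        assert rep.kappa == 0.0  # disjoint marginals make chance agreement 0

    def test_identical_constant_sequences_kappa_convention(self):
        h = Hypnogram(("N2",) * 8)
        assert stage_metrics(h, h).kappa == 1.0

    def test_missing_class_rules(self):
        # N3 and REM absent from both: excluded; N1 present only in ref: F1=0.
        pred = Hypnogram(("W", "W", "N2", "N2"))
        ref = Hypnogram(("W", "N1", "N2", "N2"))
        rep = stage_metrics(pred, ref)
        assert math.isnan(rep.class_f1[3]) and math.isnan(rep.class_f1[4])
        assert rep.class_f1[1] == 0.0
        defined = [f for f in rep.class_f1 if not math.isnan(f)]
        assert rep.macro_f1 == pytest.approx(sum(defined) / len(defined))

    def test_dropping_a_class_strictly_decreases_mf1(self):
        ref = Hypnogram(("W", "N1", "N2", "N3", "REM") * 4)
        degraded = Hypnogram(tuple(
            "N2" if t == "N1" else t for t in ref.labels
        ))
        assert stage_metrics(degraded, ref).macro_f1 < 1.0

    def test_matches_brute_force_confusion_oracle(self, rng):
        pred = random_hypnogram(rng, 500)
        ref = random_hypnogram(rng, 500)
        rep = stage_metrics(pred, ref)
        # independent oracle: explicit confusion counts and formulas
        cm = np.zeros((5, 5))
        for p, r in zip(pred.stages, ref.stages):
            cm[r, p] += 1
        n = cm.sum()
        acc = np.trace(cm) / n
        pe = sum(cm[c].sum() * cm[:, c].sum() for c in range(5)) / n**2
        kappa = (acc - pe) / (1 - pe)
        f1 = []
        for c in range(5):
            tp = cm[c, c]
            fp = cm[:, c].sum() - tp
            fn = cm[c].sum() - tp
            f1.append(2 * tp / (2 * tp + fp + fn))
        assert rep.accuracy == pytest.approx(acc, abs=1e-12)
        assert rep.kappa == pytest.approx(kappa, abs=1e-12)
        assert rep.macro_f1 == pytest.approx(np.mean(f1), abs=1e-12)

    def test_cross_checks_against_sklearn(self, rng):
        pred = random_hypnogram(rng, 400)
        ref = random_hypnogram(rng, 400)
        rep = stage_metrics(pred, ref)
        assert rep.kappa == pytest.approx(
            cohen_kappa_score(ref.stages, pred.stages), abs=1e-12
        )
        assert rep.macro_f1 == pytest.approx(
            f1_score(ref.stages, pred.stages, average="macro"), abs=1e-12
        )

    def test_masked_epochs_are_excluded(self):
        pred = Hypnogram(("W", "N2", "N2"))
        ref = Hypnogram(("W", "MOVEMENT", "N2"))
        assert stage_metrics(pred, ref).accuracy == 1.0


class TestAggregate:
    def test_single_recording_mean_is_its_metric(self, rng):
        pred, ref = random_hypnogram(rng, 100), random_hypnogram(rng, 100)
        df = aggregate([(pred, ref)], level="recording")
        single = stage_metrics(pred, ref)
        assert df.loc["mean", "accuracy"] == pytest.approx(single.accuracy)
        assert df.loc["sd", "accuracy"] == 0.0

    def test_equal_length_recordings_pool_to_mean_accuracy(self, rng):
        pairs = [
            (random_hypnogram(rng, 150), random_hypnogram(rng, 150))
            for _ in range(2)
        ]
        pooled = aggregate(pairs, level="dataset")
        per_rec = [stage_metrics(p, r).accuracy for p, r in pairs]
        assert pooled.loc["dataset", "accuracy"] == pytest.approx(
            np.mean(per_rec), abs=1e-12
        )

    def test_pooled_confusion_is_sum_of_per_recording(self, rng):
        pairs = [
            (random_hypnogram(rng, 80), random_hypnogram(rng, 80))
            for _ in range(3)
        ]
        total = sum(confusion_matrix(p, r) for p, r in pairs)
        rep = metrics_from_confusion(total)
        assert rep.support == tuple(int(x) for x in total.sum(axis=1))


def exact_signed_rank_p(diff: np.ndarray) -> float:
    """Full enumeration of the one-sided (greater) signed-rank null."""
    d = diff[diff != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs:
            count += 1
    return count / 2**n


class TestPairedCompare:
    def _matrix(self, ref, other):
        return pd.DataFrame({"ref": ref, "m": other})

    def test_identical_method_is_degenerate_with_p_one(self):
        vals = np.linspace(0.5, 0.9, 10)
        out = paired_compare(self._matrix(vals, vals), "ref")
        assert out.loc["m", "p_raw"] == 1.0
        assert out.loc["m", "r"] == 0.0
        assert bool(out.loc["m", "degenerate"])

    def test_uniformly_better_method_hits_exact_tail(self):
        ref = np.linspace(0.5, 0.9, 10)
        out = paired_compare(self._matrix(ref, ref + 0.01), "ref")
        assert out.loc["m", "p_raw"] == pytest.approx(1 / 2**10, rel=1e-12)

    def test_exact_p_matches_full_enumeration(self, rng):
        for n in (8, 11):
            ref = rng.normal(size=n)
            other = ref + rng.normal(scale=0.7, size=n)
            # regenerate until no ties in |diff| (a.s. immediate for floats)
            out = paired_compare(self._matrix(ref, other), "ref")
            assert out.loc["m", "p_raw"] == pytest.approx(
                exact_signed_rank_p(other - ref), rel=1e-12
            )

    def test_holm_adjustment_matches_hand_computation(self):
        adjusted = holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(adjusted, [0.03, 0.06, 0.06])

    def test_adjusted_p_at_least_raw_and_r_bounded(self, rng):
        ref = rng.normal(size=12)
        df = pd.DataFrame(
            {"ref": ref, "a": ref + rng.normal(size=12), "b": ref - 0.1}
        )
        out = paired_compare(df, "ref")
        assert (out["p_holm"] >= out["p_raw"] - 1e-15).all()
        assert out["r"].between(-1, 1).all()

    def test_too_few_recordings_rejected(self):
        with pytest.raises(ValueError):
            paired_compare(self._matrix(np.ones(4), np.zeros(4)), "ref")
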