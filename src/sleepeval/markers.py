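"""Hypnogram-derived clinical sleep markers and their prediction errors.

Markers computed from a single hypnogram:

* TST — total sleep time, minutes spent in N1/N2/N3/REM;
* WASO — wake after sleep onset, minutes of W strictly between sleep
  onset and the last sleep epoch;
* per-stage durations (N1, N2, N3, REM) in minutes;
* REML — REM latency, minutes from sleep onset to the first REM epoch;
* AwH — awakenings per hour of TST (an awakening is a maximal run of W
  epochs strictly inside the sleep period);
* TrH — stage transitions per hour of TST (changes between consecutive
  unmasked epochs within the sleep period);
* sleep efficiency — TST over total recording time.

Conventions: sleep onset is the first unmasked non-W epoch; masked
epochs are excluded from all duration sums and break runs, so no
awakening or transition is counted across a masked gap. Markers that
are undefined for a recording (e.g. REML with no REM sleep, rates with
TST = 0) are NaN, never raised. Bias audits model the per-marker
differences prediction minus reference between two hypnograms of the
same recording.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .hypnodata import STAGE_INDEX, Hypnogram

__all__ = ["MarkerSet", "MarkerDelta", "sleep_markers", "marker_differences"]

_W = STAGE_INDEX["W"]
_REM = STAGE_INDEX["REM"]


@dataclass(frozen=True)
class MarkerSet:
    """Clinical markers of one hypnogram. Durations in minutes, rates in
    events per hour of TST; NaN where undefined."""

    tst: float
    waso: float
    n1: float
    n2: float
    n3: float
    rem: float
    reml: float
    awh: float
    trh: float
    sleep_efficiency: float
    sleep_onset_epoch: int | None

    def as_dict(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "sleep_onset_epoch"
        }


@dataclass(frozen=True)
class MarkerDelta:
    """Per-marker differences prediction minus reference; NaN when either
    side is undefined."""

    tst: float
    waso: float
    n1: float
    n2: float
    n3: float
    rem: float
    reml: float
    awh: float
    trh: float
    sleep_efficiency: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def sleep_markers(h: Hypnogram) -> MarkerSet:
    stages = h.stages
    mask = h.mask
    minutes = h.epoch_seconds / 60.0
    live = np.nonzero(mask)[0]
    sleep_idx = live[(stages[live] != _W)]

    def dur(stage: int) -> float:
        return float(np.sum(mask & (stages == stage)) * minutes)

    n1, n2, n3, rem = (dur(s) for s in (1, 2, 3, 4))
    tst = n1 + n2 + n3 + rem
    total_minutes = h.n_epochs * minutes
    eff = tst / total_minutes

    if sleep_idx.size == 0:  # all-wake (or all-masked) recording
        return MarkerSet(
            tst=0.0, waso=0.0, n1=n1, n2=n2, n3=n3, rem=rem,
            reml=np.nan, awh=np.nan, trh=np.nan,
            sleep_efficiency=eff, sleep_onset_epoch=None,
        )

    onset = int(sleep_idx[0])
    last_sleep = int(sleep_idx[-1])

    inner = (np.arange(h.n_epochs) > onset) & (np.arange(h.n_epochs) < last_sleep)
    waso = float(np.sum(mask & inner & (stages == _W)) * minutes)

    rem_idx = live[stages[live] == _REM]
    reml = float((rem_idx[0] - onset) * minutes) if rem_idx.size else np.nan

    # Awakenings: maximal unmasked W runs strictly inside (onset, last_sleep);
    # a masked epoch breaks a run.
    awakenings = 0
    in_run = False
    for i in range(onset + 1, last_sleep):
        if mask[i] and stages[i] == _W:
            if not in_run:
                awakenings += 1
                in_run = True
        else:
            in_run = False

    # Transitions: stage changes between adjacent unmasked epochs inside
    # the sleep period [onset, last_sleep].
    transitions = 0
    for i in range(onset, last_sleep):
        if mask[i] and mask[i + 1] and stages[i] != stages[i + 1]:
            transitions += 1

    tst_hours = tst / 60.0
    awh = awakenings / tst_hours if tst_hours > 0 else np.nan
    trh = transitions / tst_hours if tst_hours > 0 else np.nan
    return MarkerSet(
        tst=tst, waso=waso, n1=n1, n2=n2, n3=n3, rem=rem,
        reml=reml, awh=awh, trh=trh,
        sleep_efficiency=eff, sleep_onset_epoch=onset,
    )


def marker_differences(pred: Hypnogram, ref: Hypnogram) -> MarkerDelta:
    """Element-wise marker differences pred - ref on a shared epoch grid.

    A marker undefined on either side propagates as NaN.
    """
    if pred.n_epochs != ref.n_epochs or pred.epoch_seconds != ref.epoch_seconds:
        raise ValueError("pred and ref must share the epoch grid")
    mp = sleep_markers(pred).as_dict()
    mr = sleep_markers(ref).as_dict()
    return MarkerDelta(**{k: mp[k] - mr[k] for k in mp})
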