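"""Data model and file I/O for hypnograms and hypnodensities.

Sleep staging assigns one of five AASM classes -- W (wake), N1, N2, N3
and REM -- to every 30-second epoch of a polysomnographic recording.
This module provides the two canonical in-memory containers used
throughout the package:

``Hypnogram``
    a discrete per-epoch stage sequence, with a boolean mask that is
    false on epochs carrying non-stage annotations (MOVEMENT, UNKNOWN);

``Hypnodensity``
    a T x 5 matrix of per-epoch stage probabilities, as produced by a
    probabilistic stager or by a soft-voting ensemble.

Legacy R&K scorings use a sixth stage N4; it is always merged into N3.
Masked epochs are excluded from every downstream per-epoch computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "STAGE_INDEX",
    "NONSTAGE_CODES",
    "StageVocabulary",
    "Hypnogram",
    "Hypnodensity",
    "MultiScorerRecord",
    "read_hypnogram",
    "write_hypnogram",
    "read_hypnodensity",
    "write_hypnodensity",
    "read_manifest",
    "write_manifest",
    "to_onehot",
    "argmax_stages",
]

#: Canonical stage order used in every matrix and file of this package.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}
NONSTAGE_CODES: frozenset[str] = frozenset({"MOVEMENT", "UNKNOWN"})

#: Row-sum tolerance below which a hypnodensity row is silently
#: renormalized; larger deviations raise (corrupt file, not float noise).
ROW_SUM_TOL = 1e-6


@dataclass(frozen=True)
class StageVocabulary:
    """The five scoreable stages, maskable codes and input alias table.

    The alias map is total over the supported dialects and
    case-insensitive; R&K N4 always resolves to N3.
    """

    stages: tuple[str, ...] = STAGES
    nonstage_codes: frozenset[str] = NONSTAGE_CODES
    aliases: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_ALIASES))

    def resolve(self, token: str) -> str:
        """Map an input token to its canonical code (stage or non-stage)."""
        key = token.strip().lower()
        try:
            return self.aliases[key]
        except KeyError:
            raise ValueError(f"unknown stage token {token!r}") from None


_DEFAULT_ALIASES: dict[str, str] = {
    "w": "W", "wake": "W", "0": "W",
    "n1": "N1", "1": "N1",
    "n2": "N2", "2": "N2",
    "n3": "N3", "3": "N3",
    "n4": "N3", "4": "N3",  # R&K N4 merged into N3
    "r": "REM", "rem": "REM", "5": "REM",
    "movement": "MOVEMENT", "m": "MOVEMENT",
    "unknown": "UNKNOWN", "?": "UNKNOWN",
}

DEFAULT_VOCABULARY = StageVocabulary()


@dataclass(frozen=True)
class Hypnogram:
    """Per-epoch stage sequence of a single recording/scorer.

    ``labels`` holds canonical tokens (members of :data:`STAGES` or
    :data:`NONSTAGE_CODES`); ``mask`` is derived: true exactly where the
    label is a scoreable stage.
    """

    labels: tuple[str, ...]
    epoch_seconds: float = 30.0
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("hypnogram must contain at least one epoch")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        bad = [t for t in self.labels if t not in STAGE_INDEX and t not in NONSTAGE_CODES]
        if bad:
            raise ValueError(f"non-canonical label(s): {sorted(set(bad))!r}")
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, true where the epoch carries a scoreable stage."""
        return np.array([t in STAGE_INDEX for t in self.labels], dtype=bool)

    @property
    def stages(self) -> np.ndarray:
        """Integer stage indices (0..4); -1 on masked epochs."""
        return np.array(
            [STAGE_INDEX.get(t, -1) for t in self.labels], dtype=np.int64
        )

    def with_source(self, source_id: str) -> "Hypnogram":
        return replace(self, source_id=source_id)

    @classmethod
    def from_stages(
        cls,
        stages: Sequence[int],
        epoch_seconds: float = 30.0,
        source_id: str = "",
        mask: Sequence[bool] | None = None,
    ) -> "Hypnogram":
        """Build from integer stage indices; masked epochs become UNKNOWN."""
        stages = np.asarray(stages, dtype=np.int64)
        labels = []
        for i, s in enumerate(stages):
            if mask is not None and not mask[i]:
                labels.append("UNKNOWN")
            else:
                labels.append(STAGES[int(s)])
        return cls(tuple(labels), epoch_seconds, source_id)


@dataclass(frozen=True)
class Hypnodensity:
    """T x 5 per-epoch stage-probability matrix.

    Unmasked rows are validated to sum to 1 within :data:`ROW_SUM_TOL`
    (and renormalized); masked rows are ignored everywhere downstream.
    """

    probs: np.ndarray
    epoch_seconds: float = 30.0
    source_id: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != len(STAGES):
            raise ValueError(f"probs must be T x {len(STAGES)}, got {probs.shape}")
        if probs.shape[0] < 1:
            raise ValueError("hypnodensity must contain at least one epoch")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        mask = (
            np.ones(probs.shape[0], dtype=bool)
            if self.mask is None
            else np.asarray(self.mask, dtype=bool)
        )
        if mask.shape != (probs.shape[0],):
            raise ValueError("mask length must equal the number of epochs")
        live = probs[mask]
        if live.size:
            if np.any(live < 0):
                raise ValueError("negative probability entry")
            sums = live.sum(axis=1)
            off = np.abs(sums - 1.0)
            if np.any(off > ROW_SUM_TOL):
                i = int(np.argmax(off))
                raise ValueError(
                    f"row sum {sums[i]:.9g} deviates from 1 by more than {ROW_SUM_TOL}"
                )
            probs = probs.copy()
            probs[mask] = live / sums[:, None]
        probs.setflags(write=False)
        mask.setflags(write=False)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "mask", mask)

    @property
    def n_epochs(self) -> int:
        return self.probs.shape[0]

    def with_source(self, source_id: str) -> "Hypnodensity":
        return replace(self, source_id=source_id)


@dataclass(frozen=True)
class MultiScorerRecord:
    """One recording with S scorer hypnograms and optionally M model
    hypnodensities, all on the same epoch grid."""

    record_id: str
    scorer_hypnograms: tuple[Hypnogram, ...]
    model_hypnodensities: tuple[Hypnodensity, ...] = ()

    def __post_init__(self) -> None:
        scorers = tuple(self.scorer_hypnograms)
        models = tuple(self.model_hypnodensities)
        if not scorers:
            raise ValueError("record needs at least one scorer hypnogram")
        t0, e0 = scorers[0].n_epochs, scorers[0].epoch_seconds
        for h in scorers:
            if h.n_epochs != t0 or h.epoch_seconds != e0:
                raise ValueError("all members must share T and epoch_seconds")
        for d in models:
            if d.n_epochs != t0 or d.epoch_seconds != e0:
                raise ValueError("all members must share T and epoch_seconds")
        ids = [h.source_id for h in scorers]
        if len(set(ids)) != len(ids):
            raise ValueError("scorer source_ids must be unique")
        object.__setattr__(self, "scorer_hypnograms", scorers)
        object.__setattr__(self, "model_hypnodensities", models)

    @property
    def n_epochs(self) -> int:
        return self.scorer_hypnograms[0].n_epochs

    @property
    def epoch_seconds(self) -> float:
        return self.scorer_hypnograms[0].epoch_seconds

    @property
    def scorer_ids(self) -> tuple[str, ...]:
        return tuple(h.source_id for h in self.scorer_hypnograms)

    def scorer(self, source_id: str) -> Hypnogram:
        for h in self.scorer_hypnograms:
            if h.source_id == source_id:
                return h
        raise KeyError(f"no scorer {source_id!r} in record {self.record_id!r}")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_DIALECTS = ("lines", "csv")


def read_hypnogram(
    path: str | Path,
    dialect: str = "lines",
    epoch_seconds: float = 30.0,
    vocabulary: StageVocabulary = DEFAULT_VOCABULARY,
    source_id: str | None = None,
) -> Hypnogram:
    """Read a hypnogram file.

    Dialects: ``lines`` (one stage token per line) and ``csv``
    (two columns ``epoch,stage``). Tokens are resolved through the
    vocabulary alias table; unresolvable tokens raise with the token and
    line number.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    text = path.read_text()
    rows: list[tuple[int, str]] = []  # (line number, raw token)
    lines = [ln for ln in text.splitlines()]
    if dialect == "lines":
        for i, ln in enumerate(lines, start=1):
            if ln.strip():
                rows.append((i, ln.strip()))
    else:
        start = 1
        if lines and lines[0].strip().lower().replace(" ", "") == "epoch,stage":
            start = 2
        for i, ln in enumerate(lines[start - 1:], start=start):
            if not ln.strip():
                continue
            parts = ln.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {i}: expected 'epoch,stage'")
            rows.append((i, parts[1].strip()))
    if not rows:
        raise ValueError(f"{path}: empty hypnogram file")
    labels = []
    for lineno, token in rows:
        try:
            labels.append(vocabulary.resolve(token))
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno}: unknown stage token {token!r}"
            ) from None
    return Hypnogram(
        tuple(labels),
        epoch_seconds=epoch_seconds,
        source_id=source_id if source_id is not None else path.stem,
    )


def write_hypnogram(h: Hypnogram, path: str | Path, dialect: str = "lines") -> None:
    """Write canonical tokens; round-trip safe with :func:`read_hypnogram`."""
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "lines":
        path.write_text("".join(f"{t}\n" for t in h.labels))
    else:
        body = "".join(f"{i},{t}\n" for i, t in enumerate(h.labels))
        path.write_text("epoch,stage\n" + body)


def read_hypnodensity(
    path: str | Path,
    epoch_seconds: float = 30.0,
    source_id: str | None = None,
) -> Hypnodensity:
    """Read a hypnodensity CSV (header ``W,N1,N2,N3,REM``, one row per epoch)."""
    path = Path(path)
    df = pd.read_csv(path)
    expected = list(STAGES)
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: expected columns {expected}, got {list(df.columns)}"
        )
    probs = df.to_numpy(dtype=float)
    return Hypnodensity(
        probs,
        epoch_seconds=epoch_seconds,
        source_id=source_id if source_id is not None else path.stem,
    )


def write_hypnodensity(d: Hypnodensity, path: str | Path) -> None:
    """Write the probability matrix as CSV with 9-significant-digit floats."""
    df = pd.DataFrame(np.asarray(d.probs), columns=list(STAGES))
    df.to_csv(path, index=False, float_format="%.9g")


def read_manifest(path: str | Path) -> list[MultiScorerRecord]:
    """Load a JSON manifest grouping scorer/model files per recording.

    Schema: a list of objects
    ``{record_id, epoch_seconds, scorers: [{id, path}], models: [{id, path}]}``;
    relative paths resolve against the manifest's directory.
    """
    path = Path(path)
    entries = json.loads(path.read_text())
    base = path.parent
    records = []
    for entry in entries:
        eps = float(entry.get("epoch_seconds", 30.0))
        scorers = tuple(
            read_hypnogram(
                base / s["path"],
                dialect=s.get("dialect", "lines"),
                epoch_seconds=eps,
                source_id=s["id"],
            )
            for s in entry["scorers"]
        )
        models = tuple(
            read_hypnodensity(base / m["path"], epoch_seconds=eps, source_id=m["id"])
            for m in entry.get("models", [])
        )
        records.append(MultiScorerRecord(entry["record_id"], scorers, models))
    return records


def write_manifest(
    records: Iterable[MultiScorerRecord], directory: str | Path
) -> Path:
    """Write each record's members as files plus a ``manifest.json`` index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in records:
        scorers = []
        for h in rec.scorer_hypnograms:
            fname = f"{rec.record_id}_{h.source_id}.hyp"
            write_hypnogram(h, directory / fname)
            scorers.append({"id": h.source_id, "path": fname, "dialect": "lines"})
        models = []
        for d in rec.model_hypnodensities:
            fname = f"{rec.record_id}_{d.source_id}.csv"
            write_hypnodensity(d, directory / fname)
            models.append({"id": d.source_id, "path": fname})
        entries.append(
            {
                "record_id": rec.record_id,
                "epoch_seconds": rec.epoch_seconds,
                "scorers": scorers,
                "models": models,
            }
        )
    out = directory / "manifest.json"
    out.write_text(json.dumps(entries, indent=2))
    return out


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------


def to_onehot(h: Hypnogram) -> Hypnodensity:
    """One-hot encode a hypnogram; masked epochs yield masked zero rows."""
    idx = h.stages
    probs = np.zeros((h.n_epochs, len(STAGES)))
    live = idx >= 0
    probs[np.nonzero(live)[0], idx[live]] = 1.0
    return Hypnodensity(
        probs, epoch_seconds=h.epoch_seconds, source_id=h.source_id, mask=live
    )


def argmax_stages(
    d: Hypnodensity,
    tiebreak: str = "lowest",
    reference: Hypnogram | None = None,
) -> Hypnogram:
    """Discretize a hypnodensity by per-epoch argmax.

    Ties go to the lowest stage index (``tiebreak="lowest"``, the
    default) or to an external reference hypnogram's label when it is
    among the tied stages (``tiebreak="reference"``). Masked epochs stay
    masked (UNKNOWN).
    """
    probs = np.asarray(d.probs)
    if tiebreak not in ("lowest", "reference"):
        raise ValueError("tiebreak must be 'lowest' or 'reference'")
    if tiebreak == "reference" and reference is None:
        raise ValueError("tiebreak='reference' requires a reference hypnogram")
    stages = probs.argmax(axis=1)  # np.argmax returns the lowest tied index
    if tiebreak == "reference":
        ref_idx = reference.stages
        row_max = probs.max(axis=1)
        for t in range(probs.shape[0]):
            tied = np.nonzero(probs[t] == row_max[t])[0]
            if tied.size > 1 and ref_idx[t] in tied:
                stages[t] = ref_idx[t]
    return Hypnogram.from_stages(
        stages,
        epoch_seconds=d.epoch_seconds,
        source_id=d.source_id,
        mask=d.mask,
    )
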