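"""Per-trial data model and delimited-text I/O for the two-interval
temporal-bisection paradigm with a second-order (metacognitive) choice.

One *trial* is a pair of bisection estimates of the same interval followed
by a forced choice of which estimate the observer believes was closer to
the target (the veridical midpoint, ``total_duration / 2``). Internally all
times are stored in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import json
import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "CONDITIONS",
    "ScheduleSpec",
    "TrialRecord",
    "SessionDataset",
    "SchemaError",
    "ValidationError",
    "read_trials",
    "write_trials",
    "ideal_choice",
]

#: Canonical column order for the on-disk CSV representation.
COLUMNS = (
    "subject_id",
    "condition",
    "total_duration",
    "trial_index",
    "estimate1",
    "estimate2",
    "meta_choice",
    "feedback_correct",
)

#: Recognised modality labels: visual, auditory, audio-visual.
CONDITIONS = ("V", "A", "AV")


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """A row violates a trial-record invariant."""


@dataclass(frozen=True)
class ScheduleSpec:
    """Trial schedule of one experimental session.

    Defaults mirror the paradigm: 500 trials in blocks of 100, a random
    pre-stimulus delay of 0-250 ms, a 500 ms inter-stimulus interval, and
    auditory feedback on whether the chosen interval was the closer one.
    """

    n_trials: int = 500
    block_size: int = 100
    jitter_range: tuple[float, float] = (0.0, 0.250)
    isi: float = 0.500
    feedback: bool = True

    def __post_init__(self) -> None:
        if self.n_trials < 0:
            raise ValueError("n_trials must be nonnegative")
        if self.block_size > 0 and self.n_trials % self.block_size:
            raise ValueError(
                f"n_trials={self.n_trials} is not a multiple of "
                f"block_size={self.block_size}"
            )
        lo, hi = self.jitter_range
        if not (0 <= lo <= hi):
            raise ValueError("jitter_range must be 0 <= lo <= hi")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["jitter_range"] = list(self.jitter_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScheduleSpec":
        d = dict(d)
        if "jitter_range" in d:
            d["jitter_range"] = tuple(d["jitter_range"])
        return cls(**d)


@dataclass(frozen=True)
class TrialRecord:
    """A single trial pair: two bisection estimates plus the type-2 choice."""

    subject_id: str
    condition: str
    total_duration: float  # seconds
    trial_index: int  # 1-based within subject-condition-duration
    estimate1: float  # seconds, interval-1 bisection
    estimate2: float  # seconds, interval-2 bisection
    meta_choice: int  # 1 or 2: interval deemed closest to target
    feedback_correct: bool | None = None

    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition {self.condition!r} not in {CONDITIONS}"
            )
        if not self.total_duration > 0:
            raise ValidationError("total_duration must be positive")
        if self.trial_index < 1:
            raise ValidationError("trial_index must be >= 1")
        for name in ("estimate1", "estimate2"):
            v = getattr(self, name)
            if not (0.0 <= v <= self.total_duration):
                raise ValidationError(
                    f"{name}={v} outside [0, {self.total_duration}]"
                )
        if self.meta_choice not in (1, 2):
            raise ValidationError(f"meta_choice must be 1 or 2, got {self.meta_choice}")


def ideal_choice(estimate1: float, estimate2: float, total_duration: float):
    """Interval (1 or 2) whose estimate is closer to the veridical midpoint.

    Ties break toward interval 1 (a measure-zero event for continuous data).
    """
    mid = total_duration / 2.0
    return np.where(np.abs(np.asarray(estimate2) - mid)
                    < np.abs(np.asarray(estimate1) - mid), 2, 1)


@dataclass
class SessionDataset:
    """An ordered collection of trial records plus schedule metadata.

    The primary container is a pandas DataFrame with the columns of
    :data:`COLUMNS`; ``records`` offers a dataclass view when convenient.
    """

    frame: pd.DataFrame
    schedule: ScheduleSpec = field(default_factory=ScheduleSpec)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[TrialRecord], schedule: ScheduleSpec | None = None
    ) -> "SessionDataset":
        rows = []
        for r in records:
            r.validate()
            rows.append(asdict(r))
        frame = pd.DataFrame(rows, columns=list(COLUMNS))
        ds = cls(frame, schedule or ScheduleSpec(n_trials=len(rows), block_size=0))
        ds._recompute_feedback()
        ds.validate()
        return ds

    def _recompute_feedback(self) -> None:
        # feedback_correct is derived, never trusted: the ideal choice is the
        # interval with the smaller absolute error to total_duration/2.
        f = self.frame
        if len(f) == 0:
            f["feedback_correct"] = pd.Series(dtype=bool)
            return
        ideal = ideal_choice(
            f["estimate1"].to_numpy(),
            f["estimate2"].to_numpy(),
            f["total_duration"].to_numpy(),
        )
        f["feedback_correct"] = f["meta_choice"].to_numpy() == ideal

    # -- validation --------------------------------------------------------

    def validate(self) -> "SessionDataset":
        f = self.frame
        missing = [c for c in COLUMNS if c not in f.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        bad_cond = ~f["condition"].isin(CONDITIONS)
        if bad_cond.any():
            raise ValidationError(
                f"unknown condition at row {int(np.flatnonzero(bad_cond)[0])}"
            )
        if (f["total_duration"] <= 0).any():
            row = int(np.flatnonzero(f["total_duration"] <= 0)[0])
            raise ValidationError(f"nonpositive total_duration at row {row}")
        for name in ("estimate1", "estimate2"):
            bad = (f[name] < 0) | (f[name] > f["total_duration"])
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"{name} outside [0, total_duration] at row {row}"
                )
        if (~f["meta_choice"].isin([1, 2])).any():
            row = int(np.flatnonzero(~f["meta_choice"].isin([1, 2]))[0])
            raise ValidationError(f"meta_choice not in {{1, 2}} at row {row}")
        dup = f.duplicated(subset=["subject_id", "condition", "total_duration", "trial_index"])
        if dup.any():
            row = int(np.flatnonzero(dup)[0])
            raise ValidationError(f"duplicate trial_index at row {row}")
        return self

    # -- convenience -------------------------------------------------------

    @property
    def records(self) -> list[TrialRecord]:
        return [
            TrialRecord(
                subject_id=str(r.subject_id),
                condition=str(r.condition),
                total_duration=float(r.total_duration),
                trial_index=int(r.trial_index),
                estimate1=float(r.estimate1),
                estimate2=float(r.estimate2),
                meta_choice=int(r.meta_choice),
                feedback_correct=bool(r.feedback_correct),
            )
            for r in self.frame.itertuples(index=False)
        ]

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, subject_id=None, condition=None, total_duration=None) -> "SessionDataset":
        """Slice by subject / condition / duration, preserving trial order."""
        f = self.frame
        mask = pd.Series(True, index=f.index)
        if subject_id is not None:
            mask &= f["subject_id"] == subject_id
        if condition is not None:
            mask &= f["condition"] == condition
        if total_duration is not None:
            mask &= np.isclose(f["total_duration"], total_duration)
        return SessionDataset(f[mask].reset_index(drop=True), self.schedule)

    def concat(self, other: "SessionDataset") -> "SessionDataset":
        return SessionDataset(
            pd.concat([self.frame, other.frame], ignore_index=True), self.schedule
        )


def read_trials(
    path,
    delimiter: str = ",",
    units: str = "s",
    schedule: ScheduleSpec | None = None,
) -> SessionDataset:
    """Read a per-trial table from delimited text.

    Parameters
    ----------
    path : str or path-like
        CSV file with a header naming the :data:`COLUMNS` fields
        (``feedback_correct`` may be absent; it is recomputed regardless).
    delimiter : str
        Field delimiter, comma by default.
    units : {"s", "ms"}
        Unit of the duration/estimate columns in the file; values are
        normalised to seconds internally.
    schedule : ScheduleSpec, optional
        Schedule metadata. If omitted, a JSON sidecar ``<path>.schedule.json``
        is read when present, else a block-free schedule is inferred.
    """
    if units not in ("s", "ms"):
        raise ValueError("units must be 's' or 'ms'")
    frame = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
    required = [c for c in COLUMNS if c != "feedback_correct"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    if units == "ms":
        for c in ("total_duration", "estimate1", "estimate2"):
            frame[c] = frame[c] / 1000.0
    frame["subject_id"] = frame["subject_id"].astype(str)
    for c in ("total_duration", "estimate1", "estimate2"):
        frame[c] = frame[c].astype(float)
    frame["trial_index"] = frame["trial_index"].astype(int)
    frame["meta_choice"] = frame["meta_choice"].astype(int)
    frame = frame.reindex(columns=list(COLUMNS))

    if schedule is None:
        sidecar = str(path) + ".schedule.json"
        try:
            with open(sidecar) as fh:
                schedule = ScheduleSpec.from_dict(json.load(fh))
        except FileNotFoundError:
            n = int(
                frame.groupby(["subject_id", "condition", "total_duration"])
                .size().max()
            ) if len(frame) else 0
            schedule = ScheduleSpec(n_trials=n, block_size=0)

    ds = SessionDataset(frame, schedule)
    ds._recompute_feedback()
    return ds.validate()


def write_trials(
    data: SessionDataset, path, delimiter: str = ",", sidecar: bool = True
) -> None:
    """Write a validated dataset as delimited text.

    Floats are rendered with 17 significant digits so that a
    write -> read round trip reproduces every value bit-exactly. Schedule
    metadata goes to a JSON sidecar ``<path>.schedule.json``.
    """
    data.validate()
    frame = data.frame.reindex(columns=list(COLUMNS))
    frame.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
    if sidecar:
        with open(str(path) + ".schedule.json", "w") as fh:
            json.dump(data.schedule.to_dict(), fh, indent=1)
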