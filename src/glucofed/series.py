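"""Core per-patient time-series containers.

A patient's record lives on a regular CGM grid (default 5-minute
sampling): glucose in mmol/L with explicit NaN for missing readings,
plus discrete insulin (bolus, basal-rate change) and meal events.
Timestamps are integer minutes relative to the series start — no
calendar dates, so there is no timezone or DST ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

EVENT_KINDS = ("glucose", "bolus", "basal", "meal")

TRAIN, TEST = "train", "test"


@dataclass(frozen=True)
class EventRecord:
    """A single discrete event.

    value units: glucose mmol/L, bolus mU, basal mU/min, meal grams of
    carbohydrate.
    """

    timestamp: int
    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.timestamp < 0:
            raise ValueError("event timestamp must be >= 0")
        if self.value < 0:
            raise ValueError(f"{self.kind} value must be non-negative")


@dataclass
class PatientSeries:
    """One patient's gridded glucose plus event lists and train/test tags.

    ``glucose`` has one entry per grid timestamp in ``t``; missing CGM
    readings are NaN and are never imputed (downstream windowing simply
    discards samples that touch them).
    """

    patient_id: str
    delta_t: int
    t: np.ndarray                 # int minutes, strictly increasing grid
    glucose: np.ndarray           # mmol/L, NaN = missing reading
    insulin_events: list[EventRecord] = field(default_factory=list)
    meal_events: list[EventRecord] = field(default_factory=list)
    split: np.ndarray | None = None   # per-timestamp "train"/"test"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.glucose.shape:
            raise ValueError("t and glucose must be 1-D and the same length")
        if len(self.t) and (np.any(np.diff(self.t) <= 0)):
            raise ValueError("grid timestamps must be strictly increasing")
        if len(self.t) and np.any(self.t % self.delta_t != 0):
            raise ValueError(f"timestamps must be multiples of delta_t={self.delta_t}")
        span_lo, span_hi = (int(self.t[0]), int(self.t[-1])) if len(self.t) else (0, 0)
        # canonical event order makes IO round-trips order-insensitive
        self.insulin_events = sorted(self.insulin_events,
                                     key=lambda e: (e.timestamp, e.kind, e.value))
        self.meal_events = sorted(self.meal_events,
                                  key=lambda e: (e.timestamp, e.kind, e.value))
        for ev in list(self.insulin_events) + list(self.meal_events):
            if not (span_lo <= ev.timestamp <= span_hi):
                raise ValueError(
                    f"event at t={ev.timestamp} outside series span "
                    f"[{span_lo}, {span_hi}]")
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)
            if self.split.shape != self.t.shape:
                raise ValueError("split must tag every grid timestamp")
            is_test = self.split == TEST
            if is_test.any() and not is_test[np.argmax(is_test):].all():
                raise ValueError("all train timestamps must precede test timestamps")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatientSeries):
            return NotImplemented
        same_split = (
            (self.split is None and other.split is None)
            or (self.split is not None and other.split is not None
                and np.array_equal(self.split, other.split))
        )
        return (
            self.patient_id == other.patient_id
            and self.delta_t == other.delta_t
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.glucose, other.glucose, equal_nan=True)
            and self.insulin_events == other.insulin_events
            and self.meal_events == other.meal_events
            and same_split
        )

    @property
    def n_points(self) -> int:
        return len(self.t)

    def copy(self) -> "PatientSeries":
        return replace(
            self,
            t=self.t.copy(),
            glucose=self.glucose.copy(),
            insulin_events=list(self.insulin_events),
            meal_events=list(self.meal_events),
            split=None if self.split is None else self.split.copy(),
        )


def assign_split(series: PatientSeries, test_fraction: float) -> PatientSeries:
    """Tag the chronologically final ``test_fraction`` of the grid as test.

    The boundary floors on the train side: with an odd count and fraction
    0.5 the test segment is the larger half.  Never shuffles.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    out = series.copy()
    n = out.n_points
    n_train = int(np.floor(n * (1 - test_fraction)))
    tags = np.array([TRAIN] * n_train + [TEST] * (n - n_train), dtype=object)
    out.split = tags
    return out
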