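"""Baseline removal, prefrontal differencing and timeslot extraction.

Valence-related activity shows up as a left/right imbalance between the
prefrontal sites: positive affect is associated with relatively stronger
left-frontal activity, negative affect with right-frontal activity. The
pipeline therefore collapses the Fp1/Fp2 pair into a single difference
series (Fp1 - Fp2) and computes all features from it. Differencing is done
before band filtering; the two operations commute for linear filters, and
differencing first halves the filtering work.

Sample indexing is 0-based and time windows are half-open ``[t0, t1)`` so
that consecutive timeslots partition a recording without overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical 20-second timeslots of a 60 s post-baseline trial, in seconds.
NAMED_TIMESLOTS = {
    "first20": (0.0, 20.0),
    "middle20": (20.0, 40.0),
    "last20": (40.0, 60.0),
    "full60": (0.0, 60.0),
}


@dataclass(frozen=True)
class TimeslotSpec:
    """A half-open window ``[t0, t1)`` in seconds after baseline removal."""

    name: str
    t0: float
    t1: float

    def __post_init__(self) -> None:
        if not 0 <= self.t0 < self.t1:
            raise ValueError(f"need 0 <= t0 < t1, got [{self.t0}, {self.t1})")

    @classmethod
    def named(cls, name: str) -> "TimeslotSpec":
        if name not in NAMED_TIMESLOTS:
            raise ValueError(
                f"unknown timeslot {name!r}; options: {sorted(NAMED_TIMESLOTS)}"
            )
        t0, t1 = NAMED_TIMESLOTS[name]
        return cls(name, t0, t1)

    @classmethod
    def parse(cls, text: str) -> "TimeslotSpec":
        """Parse ``first20``-style names or a custom ``t0:t1`` in seconds."""
        if text in NAMED_TIMESLOTS:
            return cls.named(text)
        try:
            t0, t1 = (float(part) for part in text.split(":"))
        except ValueError:
            raise ValueError(
                f"cannot parse timeslot {text!r}; expected a named slot "
                f"({sorted(NAMED_TIMESLOTS)}) or 't0:t1' seconds"
            ) from None
        return cls("custom", t0, t1)


FULL60 = TimeslotSpec.named("full60")


def drop_baseline(series: np.ndarray, fs: float, baseline_s: float) -> np.ndarray:
    """Remove the leading pre-trial baseline from a 1-D sample series.

    The baseline segment is discarded outright (no baseline-statistic
    subtraction). For the DEAP geometry (63 s at 128 Hz, 3 s baseline)
    this maps 8064 samples to 7680.
    """
    series = np.asarray(series)
    n_drop = int(round(baseline_s * fs))
    if n_drop < 0:
        raise ValueError("baseline duration cannot be negative")
    if n_drop > series.shape[-1]:
        raise ValueError(
            f"baseline of {n_drop} samples exceeds series length "
            f"{series.shape[-1]}"
        )
    return series[..., n_drop:]


def channel_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Element-wise difference ``a - b`` (Fp1 minus Fp2 by convention)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return a - b


def extract_timeslot(
    series: np.ndarray, fs: float, slot: TimeslotSpec
) -> np.ndarray:
    """Samples in ``[round(t0*fs), round(t1*fs))`` of a 1-D series."""
    series = np.asarray(series)
    i0 = int(round(slot.t0 * fs))
    i1 = int(round(slot.t1 * fs))
    if i1 > series.shape[-1]:
        raise ValueError(
            f"timeslot [{slot.t0}, {slot.t1}) s needs {i1} samples; "
            f"series has {series.shape[-1]}"
        )
    return series[..., i0:i1]
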