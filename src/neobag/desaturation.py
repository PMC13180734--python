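"""Oxygen-desaturation events from the pulse-oximetry (SpO2) trace.

A desaturation event is a maximal contiguous run of samples with
saturation strictly below 80% lasting at least 10 s.  Runs are episodes,
not overlapping sliding windows, so the event count yields a rate in
events per hour.  Missing samples (NaN) break runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DESAT_THRESHOLD_PCT = 80.0
MIN_EVENT_DURATION_S = 10.0


@dataclass(frozen=True)
class SpO2Signal:
    """Uniformly sampled oxygen-saturation trace in percent."""

    samples: np.ndarray
    fs: float = 0.97
    start_time: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        finite = self.samples[np.isfinite(self.samples)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("saturation values must lie in [0, 100] or be NaN")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class DesatEvent:
    start_time: float
    duration: float

    def __post_init__(self):
        if self.duration < MIN_EVENT_DURATION_S:
            raise ValueError("desaturation events must last at least 10 s")


def detect_desaturations(sig: SpO2Signal,
                         threshold_pct: float = DESAT_THRESHOLD_PCT,
                         min_duration_s: float = MIN_EVENT_DURATION_S
                         ) -> list[DesatEvent]:
    """Find maximal sub-threshold runs lasting at least ``min_duration_s``."""
    x = sig.samples
    if x.size == 0 or not np.any(np.isfinite(x)):
        raise ValueError("SpO2 trace contains no valid samples")
    below = np.isfinite(x) & (x < threshold_pct)
    # run-length encode
    edges = np.flatnonzero(np.diff(np.concatenate([[0], below.astype(int), [0]])))
    starts, stops = edges[::2], edges[1::2]
    events = []
    for i0, i1 in zip(starts, stops):
        dur = (i1 - i0) / sig.fs
        if dur >= min_duration_s:
            events.append(DesatEvent(start_time=sig.start_time + i0 / sig.fs,
                                     duration=float(dur)))
    return events


def desat_rate(events: list[DesatEvent], duration_h: float) -> float:
    """Desaturation events per hour."""
    if duration_h <= 0:
        raise ValueError("recording duration must be positive")
    return len(events) / duration_h
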