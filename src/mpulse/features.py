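"""The 15 passive behavioural features.

For each of the three sensors (battery, call, screen) five statistics are
computed over a time window:

* ``Use``   — hours of event time per observed hour (dimensionless);
* ``Freq``  — events per observed hour (1/h);
* ``Mean``  — mean event duration, in hours;
* ``SD``    — standard deviation of event durations, in hours;
* ``Ent``   — Shannon entropy (nats) of the distribution of event start
  times over the 24 hour-of-day bins, in [0, ln 24].

Windowing conventions: an event is counted for ``Freq``, ``Mean``, ``SD``
and ``Ent`` iff its *start* lies in the window (full duration used for the
moments); its contribution to ``Use`` is the part of its duration that
overlaps the window.  Trait-level analyses use one window spanning the full
observation period; daily analyses use the 24 h window ending at each
morning assessment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import SENSORS, EventStream

__all__ = [
    "Window",
    "FEATURE_NAMES",
    "use_per_hour",
    "freq_per_hour",
    "duration_moments",
    "occurrence_entropy",
    "extract_features",
    "daily_windows",
    "hours_to_minutes",
]

_STATS = ("Use", "Freq", "Mean", "SD", "Ent")

#: Canonical column order of the 15-slot feature vector.
FEATURE_NAMES = tuple(f"{sensor}_{stat}" for sensor in SENSORS for stat in _STATS)

_SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class Window:
    """Half-open time interval [start, end)."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window must have positive length")

    @property
    def hours(self) -> float:
        return (self.end - self.start).total_seconds() / _SECONDS_PER_HOUR

    def contains_start(self, ts: pd.Timestamp) -> bool:
        return self.start <= ts < self.end


def _in_window_events(stream: EventStream, window: Window):
    return [e for e in stream.events if window.contains_start(e.start)]


def use_per_hour(stream: EventStream, window: Window) -> float:
    """Total in-window event time divided by window length (both in hours).

    Events straddling a window edge contribute only their overlapping
    portion, so the result is an occupancy fraction (it can exceed 1 only
    when events of one sensor overlap each other).
    """
    total_s = 0.0
    for ev in stream.events:
        lo = max(ev.start, window.start)
        hi = min(ev.end, window.end)
        if hi > lo:
            total_s += (hi - lo).total_seconds()
    return total_s / _SECONDS_PER_HOUR / window.hours


def freq_per_hour(stream: EventStream, window: Window) -> float:
    """Number of events starting in the window per observed hour."""
    return len(_in_window_events(stream, window)) / window.hours


def duration_moments(stream: EventStream, window: Window) -> tuple[float, float]:
    """Sample mean and SD of in-window event durations, in hours.

    Returns ``(nan, nan)`` for zero events and ``(mean, 0.0)`` for a single
    event.  Durations are not clipped to the window; membership is decided
    by the event start.
    """
    dur_h = np.array(
        [e.duration / _SECONDS_PER_HOUR for e in _in_window_events(stream, window)]
    )
    if dur_h.size == 0:
        return (math.nan, math.nan)
    if dur_h.size == 1:
        return (float(dur_h[0]), 0.0)
    return (float(dur_h.mean()), float(dur_h.std(ddof=1)))


def occurrence_entropy(
    stream: EventStream, window: Window, base: float | None = None
) -> float:
    """Shannon entropy of event start times over 24 hour-of-day bins.

    Event starts inside the window are binned by local clock hour; with
    bin proportions p_h the entropy is −Σ p_h log p_h (0·log 0 := 0),
    natural log by default so the maximum is ln 24 ≈ 3.178.  ``nan`` for
    event-free windows.  Entropy ignores event durations entirely.
    """
    hours = [e.start.hour for e in _in_window_events(stream, window)]
    if not hours:
        return math.nan
    counts = np.bincount(hours, minlength=24)
    p = counts / counts.sum()
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def extract_features(
    streams: dict[str, EventStream] | list[EventStream],
    window: Window,
    entropy_base: float | None = None,
) -> pd.Series:
    """Assemble the 15-slot feature vector for one participant-window.

    ``streams`` maps sensor kind to that participant's cleaned stream (a
    list is accepted and keyed by each stream's sensor).  A missing sensor
    leaves its five slots as NaN with a warning.  ``Use`` and ``Freq`` are
    genuinely 0 for an event-free window; ``Mean``, ``SD`` and ``Ent`` are
    NaN there because their defining sets are empty.
    """
    if not isinstance(streams, dict):
        streams = {s.sensor: s for s in streams}
    values: dict[str, float] = {name: math.nan for name in FEATURE_NAMES}
    for sensor in SENSORS:
        stream = streams.get(sensor)
        if stream is None:
            warnings.warn(f"no {sensor} stream supplied; its features are missing")
            continue
        mean, sd = duration_moments(stream, window)
        values[f"{sensor}_Use"] = use_per_hour(stream, window)
        values[f"{sensor}_Freq"] = freq_per_hour(stream, window)
        values[f"{sensor}_Mean"] = mean
        values[f"{sensor}_SD"] = sd
        values[f"{sensor}_Ent"] = occurrence_entropy(stream, window, base=entropy_base)
    return pd.Series(values, index=list(FEATURE_NAMES), dtype=float)


def daily_windows(assessment_times: list[pd.Timestamp]) -> list[Window]:
    """One 24 h window ending at each morning assessment: [t − 24 h, t).

    Windows from irregular assessment times may overlap; that is accepted
    as-is.  Duplicate timestamps are an error.
    """
    times = list(assessment_times)
    if len(set(times)) != len(times):
        raise ValueError("duplicate assessment timestamps")
    return [Window(t - pd.Timedelta(hours=24), t) for t in times]


def hours_to_minutes(hours: float) -> float:
    """Unit helper: a mean unlock duration of 0.1 h reads as 6 minutes."""
    return hours * 60.0
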