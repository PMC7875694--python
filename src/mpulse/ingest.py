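"""Reading, validating and cleaning raw phone-sensor event logs.

The sensing system records three kinds of durative events per participant:
phone calls, battery-charging sessions, and screen-unlock sessions.  Each
event is a ``(participant, sensor, start, duration)`` record.  Two cleaning
rules are applied before feature extraction:

* battery-charging events shorter than 10 seconds are dropped (spurious
  connect/disconnect glitches);
* screen-unlock sessions longer than 2 hours are dropped (navigation or
  video playback, not checking behaviour).

Both thresholds are strict in the direction the rule names: a 10 s charging
event survives, a session of exactly 2 h survives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "SENSORS",
    "SensorEvent",
    "EventStream",
    "read_event_log",
    "write_event_log",
    "filter_battery",
    "filter_screen",
]

#: Recognised sensor kinds.
SENSORS = ("call", "battery", "screen")

#: Default cleaning thresholds, in seconds.
BATTERY_MIN_DURATION_S = 10.0
SCREEN_MAX_DURATION_S = 2 * 3600.0


@dataclass(frozen=True)
class SensorEvent:
    """One durative sensor event.

    ``start`` is a timezone-aware timestamp; ``duration`` is in seconds and
    must be non-negative.  No identity payload (phone numbers, contact names)
    is ever attached to an event.
    """

    participant_id: str
    sensor: str
    start: pd.Timestamp
    duration: float

    def __post_init__(self) -> None:
        if self.sensor not in SENSORS:
            raise ValueError(f"unknown sensor kind {self.sensor!r}")
        if self.duration < 0:
            raise ValueError(f"negative duration {self.duration!r}")
        if self.start.tzinfo is None:
            raise ValueError("event start must be timezone-aware")

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(seconds=self.duration)


@dataclass
class EventStream:
    """Time-ordered events of one sensor kind for one participant.

    ``observation_span`` bounds the period during which the sensor was
    active; every event start must lie inside it and the span must have
    positive length.
    """

    participant_id: str
    sensor: str
    events: list[SensorEvent] = field(default_factory=list)
    observation_span: tuple[pd.Timestamp, pd.Timestamp] | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.start)
        if self.observation_span is None and self.events:
            self.observation_span = (
                self.events[0].start,
                max(e.end for e in self.events),
            )
        self.validate()

    def validate(self) -> None:
        if self.sensor not in SENSORS:
            raise ValueError(f"unknown sensor kind {self.sensor!r}")
        for prev, nxt in zip(self.events, self.events[1:]):
            if nxt.start < prev.start:
                raise ValueError("events not sorted by start time")
        if self.observation_span is not None:
            lo, hi = self.observation_span
            if hi <= lo:
                raise ValueError("observation_span must have positive length")
            for ev in self.events:
                if not (lo <= ev.start <= hi):
                    raise ValueError(
                        f"event at {ev.start} outside observation span [{lo}, {hi}]"
                    )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def is_valid(self) -> bool:
        """False for degenerate streams (no events and no declared span)."""
        return self.observation_span is not None

    def durations(self) -> list[float]:
        return [e.duration for e in self.events]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [e.participant_id for e in self.events],
                "sensor": [e.sensor for e in self.events],
                "start_iso8601": [e.start.isoformat() for e in self.events],
                "duration_s": [e.duration for e in self.events],
            }
        )


def _events_from_frame(
    df: pd.DataFrame, sensor: str, source: str
) -> list[SensorEvent]:
    events: list[SensorEvent] = []
    if "notification_flag" in df.columns:
        flags = df["notification_flag"].fillna(0).astype(bool)
        df = df.loc[~flags]
    for idx, row in df.iterrows():
        try:
            start = pd.Timestamp(row["start_iso8601"])
            duration = float(row["duration_s"])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{source}: malformed row {idx}: {exc}") from exc
        if pd.isna(start) or start.tzinfo is None:
            raise ValueError(
                f"{source}: row {idx}: timestamp {row['start_iso8601']!r} "
                "is missing or not timezone-aware"
            )
        if duration < 0:
            raise ValueError(f"{source}: row {idx}: negative duration {duration}")
        events.append(
            SensorEvent(
                participant_id=str(row["participant_id"]),
                sensor=sensor,
                start=start,
                duration=duration,
            )
        )
    return events


def read_event_log(
    path: str | Path,
    sensor: str,
    observation_span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> EventStream:
    """Read one participant's event log for one sensor kind.

    Two dialects are accepted: CSV with a header row
    (``participant_id,sensor,start_iso8601,duration_s[,notification_flag]``)
    and JSON-lines with the same field names.  Rows flagged as
    notification-induced are dropped.  Events are returned sorted; the
    observation span defaults to [first start, last event end] unless given.

    Raises ``ValueError`` naming the offending row for malformed timestamps
    or negative durations.
    """
    path = Path(path)
    if sensor not in SENSORS:
        raise ValueError(f"unknown sensor kind {sensor!r}")
    if path.suffix in {".jsonl", ".ndjson"}:
        records = [json.loads(line) for line in path.read_text().splitlines() if line.strip()]
        df = pd.DataFrame(records)
    else:
        df = pd.read_csv(path)
    if df.empty:
        return EventStream(
            participant_id="", sensor=sensor, events=[], observation_span=observation_span
        )
    events = _events_from_frame(df, sensor, str(path))
    pid = events[0].participant_id if events else ""
    return EventStream(
        participant_id=pid,
        sensor=sensor,
        events=events,
        observation_span=observation_span,
    )


def write_event_log(stream: EventStream, path: str | Path) -> None:
    """Write a stream in the CSV interchange dialect (round-trips with
    :func:`read_event_log`)."""
    stream.to_frame().to_csv(path, index=False)


def _filter(
    stream: EventStream, keep: Iterable[bool]
) -> tuple[EventStream, float]:
    survivors = [e for e, k in zip(stream.events, keep) if k]
    n_in = len(stream.events)
    removed = n_in - len(survivors)
    fraction = removed / n_in if n_in else 0.0
    out = EventStream(
        participant_id=stream.participant_id,
        sensor=stream.sensor,
        events=survivors,
        observation_span=stream.observation_span,
    )
    return out, fraction


def filter_battery(
    stream: EventStream, min_duration: float = BATTERY_MIN_DURATION_S
) -> tuple[EventStream, float]:
    """Drop battery-charging events strictly shorter than ``min_duration``
    seconds.  Returns the cleaned stream and the fraction of events removed.
    """
    if stream.sensor != "battery":
        raise ValueError(f"filter_battery applied to {stream.sensor!r} stream")
    return _filter(stream, (e.duration >= min_duration for e in stream.events))


def filter_screen(
    stream: EventStream, max_duration: float = SCREEN_MAX_DURATION_S
) -> tuple[EventStream, float]:
    """Drop screen-unlock sessions strictly longer than ``max_duration``
    seconds (default 2 h).  Returns the cleaned stream and the fraction of
    events removed.
    """
    if stream.sensor != "screen":
        raise ValueError(f"filter_screen applied to {stream.sensor!r} stream")
    return _filter(stream, (e.duration <= max_duration for e in stream.events))
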