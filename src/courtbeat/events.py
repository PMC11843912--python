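"""Timestamped acoustic events and their CSV interchange format.

Every event table written or consumed by the pipeline uses the header
``time_s,label,amplitude,probability``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

EVENT_COLUMNS = ("time_s", "label", "amplitude", "probability")

IMPACT = "impact"
REBOUND = "rebound"
NOISE = "noise"
LABELS = (IMPACT, REBOUND, NOISE)


class SchemaError(ValueError):
    """Raised when an event CSV is missing a required column."""


@dataclass(frozen=True)
class EventRecord:
    """A timestamped, labeled acoustic event.

    ``probability`` is the classifier confidence for ``label`` (1.0 for
    ground-truth annotations).
    """

    time_s: float
    label: str
    amplitude: float
    probability: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


def events_to_frame(events: list[EventRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.time_s, e.label, e.amplitude, e.probability) for e in events],
        columns=list(EVENT_COLUMNS),
    )


def frame_to_events(frame: pd.DataFrame) -> list[EventRecord]:
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"event table missing column(s): {', '.join(missing)}")
    return [
        EventRecord(
            time_s=float(row.time_s),
            label=str(row.label),
            amplitude=float(row.amplitude),
            probability=float(row.probability),
        )
        for row in frame.itertuples()
    ]


def write_events_csv(events: list[EventRecord], path: str | Path) -> None:
    """Write events to CSV with the standard header, sorted by time."""
    frame = events_to_frame(sorted(events, key=lambda e: e.time_s))
    frame.to_csv(path, index=False, float_format="%.6f")


def read_events_csv(path: str | Path) -> list[EventRecord]:
    """Read an event CSV, validating the schema (missing columns are named)."""
    return frame_to_events(pd.read_csv(path))
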