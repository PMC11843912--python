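"""Rally rhythm and groundstroke executive timing.

Rally rhythm is expressed in shots per minute. Only the near player's
impacts are detected acoustically, and exactly one opponent shot falls
inside each same-player interval, so an interval of Δt seconds between
consecutive near-player impacts corresponds to an instantaneous
frequency of 120/Δt shots/min, and n near-player impacts imply 2n - 1
total rally shots. The average frequency is (2n - 1) / span x 60 over
the first-to-last-impact span. A 60/Δt convention (counting only the
detected player's shots) is available via ``per_rally_shot=False``.

Executive timing of a groundstroke is the time from the ball's ground
rebound to its impact on the strings (impact time minus rebound time,
positive by construction since rebounds are sought 0.4-1.5 s before the
impact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from courtbeat.events import IMPACT, REBOUND, EventRecord


class InsufficientDataError(ValueError):
    """Raised when fewer events are available than a computation needs."""


@dataclass(frozen=True)
class RallyReport:
    """Rhythm of one rally, from the near player's impact times."""

    impact_times_s: tuple[float, ...]
    instantaneous_freqs_spm: tuple[float, ...]
    average_freq_spm: float
    inferred_total_shots: int
    span_s: float


@dataclass(frozen=True)
class TimingRecord:
    """One stroke's executive timing."""

    impact_time_s: float
    rebound_time_s: float

    @property
    def timing_s(self) -> float:
        return self.impact_time_s - self.rebound_time_s


@dataclass(frozen=True)
class TimingSummary:
    """Median/IQR summary of a timing series with detection bookkeeping."""

    n_valid: int
    n_missing: int
    median_s: float | None
    iqr_s: float | None


def rally_rhythm(
    near_impact_times: list[float] | np.ndarray, per_rally_shot: bool = True
) -> RallyReport:
    """Compute the rally rhythm from sorted near-player impact times.

    Raises
    ------
    InsufficientDataError
        With fewer than two impacts no interval exists.
    """
    times = np.asarray(near_impact_times, dtype=np.float64)
    if len(times) < 2:
        raise InsufficientDataError("rally rhythm needs >= 2 impact times")
    if np.any(np.diff(times) <= 0):
        raise ValueError("impact times must be strictly increasing")
    per_interval = 120.0 if per_rally_shot else 60.0
    inst = per_interval / np.diff(times)
    n = len(times)
    total = 2 * n - 1 if per_rally_shot else n
    span = float(times[-1] - times[0])
    return RallyReport(
        impact_times_s=tuple(float(t) for t in times),
        instantaneous_freqs_spm=tuple(float(f) for f in inst),
        average_freq_spm=total / span * 60.0,
        inferred_total_shots=total,
        span_s=span,
    )


def pair_impact_rebound(
    events: list[EventRecord], window: tuple[float, float] = (0.4, 1.5)
) -> list[tuple[EventRecord, EventRecord | None]]:
    """Re-derive (impact, rebound) pairs from a flat event list.

    For each impact, its rebound is the rebound record inside the closed
    window ``[t - upper, t - lower]``; validated event lists contain at
    most one. Impacts without one pair with ``None``.
    """
    lower, upper = window
    impacts = sorted((e for e in events if e.label == IMPACT), key=lambda e: e.time_s)
    rebounds = [e for e in events if e.label == REBOUND]
    pairs: list[tuple[EventRecord, EventRecord | None]] = []
    for imp in impacts:
        inside = [
            r for r in rebounds if imp.time_s - upper <= r.time_s <= imp.time_s - lower
        ]
        pairs.append((imp, max(inside, key=lambda r: r.time_s) if inside else None))
    return pairs


def executive_timing(
    pairs: list[tuple[EventRecord, EventRecord | None]]
) -> list[TimingRecord]:
    """Timing records for paired events; unpaired impacts are skipped."""
    return [
        TimingRecord(impact_time_s=imp.time_s, rebound_time_s=reb.time_s)
        for imp, reb in pairs
        if reb is not None
    ]


def summarize_timing(
    records: list[TimingRecord], ground_truth_n: int | None = None
) -> TimingSummary:
    """Median and IQR (linear-interpolation quantiles) of executive timings.

    ``ground_truth_n`` is the number of strokes actually played; the
    difference from the valid count is reported as missing.
    """
    n_valid = len(records)
    n_missing = (ground_truth_n - n_valid) if ground_truth_n is not None else 0
    if n_valid == 0:
        return TimingSummary(n_valid=0, n_missing=n_missing, median_s=None, iqr_s=None)
    values = np.array([r.timing_s for r in records])
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    return TimingSummary(
        n_valid=n_valid,
        n_missing=n_missing,
        median_s=float(med),
        iqr_s=float(q3 - q1),
    )
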