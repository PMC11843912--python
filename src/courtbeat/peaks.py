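"""Rule-based candidate peak detection.

Two detectors implement the amplitude/interval rules of the timing
pipeline:

* **Rally impacts** — peaks of the *unfiltered* normalized signal whose
  absolute amplitude exceeds 0.4, at least 390 ms apart (two impacts
  cannot occur closer than that in a baseline rally).
* **Groundstroke candidates** — run on the 100-400 Hz band-passed signal:
  "lesser" candidates exceed 0.02 with a 100 ms minimum separation;
  impact candidates are the subset exceeding 0.09. Candidate rebounds for
  an impact at time *t* are the lesser candidates inside the closed
  window ``[t - 1.5, t - 0.4]`` seconds that are not themselves impact
  candidates.

When two peaks violate the minimum separation the larger survives
(greedy by descending amplitude). Peaks are local maxima of ``|x|``,
robust to waveform polarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from courtbeat.audio_io import AudioClip


@dataclass(frozen=True)
class Peak:
    """A detected candidate peak."""

    time_s: float
    amplitude: float
    candidate_kind: str = "rally_impact"  # rally_impact | gs_impact | gs_candidate


@dataclass(frozen=True)
class PeakConfig:
    """Amplitude thresholds and interval constraints for both detectors."""

    rally_amp_thresh: float = 0.4
    rally_min_sep_s: float = 0.390
    gs_impact_thresh: float = 0.09
    gs_cand_thresh: float = 0.02
    gs_min_sep_s: float = 0.100
    rebound_window: tuple[float, float] = (0.4, 1.5)  # seconds before impact

    def __post_init__(self) -> None:
        for name in ("rally_amp_thresh", "gs_impact_thresh", "gs_cand_thresh"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        lo, hi = self.rebound_window
        if not 0 <= lo < hi:
            raise ValueError("rebound_window must satisfy 0 <= lower < upper")


def _thresholded_peaks(
    x: np.ndarray, sample_rate: int, threshold: float, min_sep_s: float | None
) -> tuple[np.ndarray, np.ndarray]:
    """Indices/amplitudes of local maxima of |x| strictly above threshold.

    ``min_sep_s`` applies the greedy descending-amplitude separation rule
    (scipy's ``distance`` semantics). Returns time-sorted arrays.
    """
    env = np.abs(x)
    distance = None
    if min_sep_s is not None:
        distance = max(1, int(round(min_sep_s * sample_rate)))
    idx, props = scipy.signal.find_peaks(env, height=threshold, distance=distance)
    heights = props["peak_heights"]
    keep = heights > threshold  # strict "exceeding"
    return idx[keep], heights[keep]


def detect_rally_impacts(
    clip: AudioClip, config: PeakConfig = PeakConfig()
) -> list[Peak]:
    """Detect rally impact peaks on the unfiltered normalized signal."""
    idx, amps = _thresholded_peaks(
        clip.samples, clip.sample_rate, config.rally_amp_thresh, config.rally_min_sep_s
    )
    return [
        Peak(time_s=i / clip.sample_rate, amplitude=a, candidate_kind="rally_impact")
        for i, a in zip(idx, amps)
    ]


def detect_groundstroke_candidates(
    filtered_clip: AudioClip,
    config: PeakConfig = PeakConfig(),
    *,
    assume_filtered: bool = True,
) -> tuple[list[Peak], list[Peak]]:
    """Detect groundstroke impact and lesser candidates on a band-passed clip.

    The caller is responsible for band-pass filtering first
    (``assume_filtered`` documents that contract). Returns
    ``(impact_candidates, lesser_candidates)`` with
    ``impact_candidates`` a subset of ``lesser_candidates``: the lesser
    list applies the 0.02 threshold and 100 ms separation; impact
    candidates are its members exceeding 0.09.
    """
    if not assume_filtered:
        raise ValueError("groundstroke detection requires a band-passed clip")
    idx, amps = _thresholded_peaks(
        filtered_clip.samples,
        filtered_clip.sample_rate,
        config.gs_cand_thresh,
        config.gs_min_sep_s,
    )
    lesser = [
        Peak(
            time_s=i / filtered_clip.sample_rate,
            amplitude=a,
            candidate_kind="gs_candidate",
        )
        for i, a in zip(idx, amps)
    ]
    impacts = [
        Peak(time_s=p.time_s, amplitude=p.amplitude, candidate_kind="gs_impact")
        for p in lesser
        if p.amplitude > config.gs_impact_thresh
    ]
    return impacts, lesser


def window_rebound_candidates(
    impacts: list[Peak],
    lesser_candidates: list[Peak],
    config: PeakConfig = PeakConfig(),
) -> dict[float, list[Peak]]:
    """Assign candidate rebounds to each impact.

    For an impact at time *t*, candidates with time in the closed
    interval ``[t - upper, t - lower]`` (defaults ``[t-1.5, t-0.4]``)
    are assigned, excluding peaks that are themselves impact candidates.
    Keys are impact times.
    """
    lower, upper = config.rebound_window
    impact_times = {p.time_s for p in impacts}
    out: dict[float, list[Peak]] = {}
    for imp in impacts:
        out[imp.time_s] = [
            c
            for c in lesser_candidates
            if imp.time_s - upper <= c.time_s <= imp.time_s - lower
            and c.time_s not in impact_times
        ]
    return out
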