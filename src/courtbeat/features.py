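"""Time- and frequency-domain feature extraction for candidate segments.

The *base* feature set, used by the impact-vs-noise classifier, combines
per-bin spectrogram statistics (mean, standard deviation, maximum per
frequency bin), the frequency of maximum energy, zero-crossing rate,
spectral centroid, 13 MFCCs (frame averages), overall time-domain
mean/std, and min/max/mean/std over short time windows.

The *extended* set, needed to separate the faint ground rebound from
ambient noise, appends tonnetz (6-dimensional harmonic-network
projection of chroma), per-band spectral contrast (peak-valley spread),
and 12 chroma bins (spectral energy folded into pitch classes,
normalized per frame).

Feature selection uses the ANOVA F-test (one-way F = MS_between /
MS_within per feature), keeping the top-k features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import f_classif

from courtbeat.audio_io import AudioClip
from courtbeat.dsp import Spectrogram, stft_spectrogram

_EPS = 1e-10


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction parameters; fixed config implies fixed vector length."""

    window_len: int = 320
    hop: int = 160
    pad_to: int = 512
    n_mfcc: int = 13
    n_mels: int = 26
    n_chroma: int = 12
    n_contrast_bands: int = 6
    n_time_windows: int = 10
    # the harmonic blocks (chroma/tonnetz/contrast) need finer frequency
    # resolution than the 320-sample detection window can give (~150 Hz);
    # they use their own longer analysis window
    harmonic_window_len: int = 1024
    harmonic_hop: int = 512
    harmonic_pad_to: int = 2048


@dataclass(frozen=True)
class FeatureVector:
    """Ordered, named feature values for one audio segment."""

    names: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")


def extract_segment(
    clip: AudioClip, peak_time: float, pre_s: float = 0.05, post_s: float = 0.25
) -> AudioClip:
    """Fixed-length segment around a peak, zero-padded at clip edges.

    The returned clip always spans ``pre_s + post_s`` seconds with the
    peak located ``pre_s`` from its start.
    """
    sr = clip.sample_rate
    n = int(round((pre_s + post_s) * sr))
    start = int(round((peak_time - pre_s) * sr))
    out = np.zeros(n)
    src_lo = max(start, 0)
    src_hi = min(start + n, len(clip.samples))
    if src_hi > src_lo:
        out[src_lo - start : src_hi - start] = clip.samples[src_lo:src_hi]
    return AudioClip(samples=out, sample_rate=sr)


# ---------------------------------------------------------------------------
# spectral helpers


def zero_crossing_rate(x: np.ndarray) -> float:
    """Fraction of consecutive sample pairs whose signs differ."""
    if len(x) < 2:
        return 0.0
    signs = np.signbit(x)
    return float(np.mean(signs[1:] != signs[:-1]))


def spectral_centroid(spec: Spectrogram) -> float:
    """Magnitude-weighted mean frequency (Hz); 0 for an all-zero segment."""
    mean_mag = spec.magnitudes.mean(axis=1)
    total = mean_mag.sum()
    if total <= 0:
        return 0.0
    return float((spec.bin_freqs_hz * mean_mag).sum() / total)


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, pad_to: int, sample_rate: int
) -> np.ndarray:
    """Triangular mel filterbank, (n_mels, n_bins)."""
    n_bins = pad_to // 2 + 1
    freqs = np.fft.rfftfreq(pad_to, d=1.0 / sample_rate)
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(sample_rate / 2), n_mels + 2)
    hz_pts = np.asarray(_mel_to_hz(mel_pts))
    fb = np.zeros((n_mels, n_bins))
    for i in range(n_mels):
        lo, mid, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        rising = (freqs - lo) / max(mid - lo, _EPS)
        falling = (hi - freqs) / max(hi - mid, _EPS)
        fb[i] = np.maximum(0.0, np.minimum(rising, falling))
    return fb


def mfcc(spec: Spectrogram, sample_rate: int, n_mfcc: int, n_mels: int) -> np.ndarray:
    """Frame-averaged MFCCs from a magnitude spectrogram."""
    power = spec.magnitudes**2  # (bins, frames)
    fb = mel_filterbank(n_mels, spec.pad_to, sample_rate)
    log_mel = np.log(fb @ power + _EPS)  # (n_mels, frames)
    cepstra = scipy.fft.dct(log_mel, type=2, axis=0, norm="ortho")[:n_mfcc]
    return cepstra.mean(axis=1)


def chroma(spec: Spectrogram, n_chroma: int = 12) -> np.ndarray:
    """Spectral energy folded into pitch classes, normalized per frame.

    Bin *f* maps to pitch class ``round(12 log2(f/440)) mod 12`` (class 9
    = A). Frames with no energy stay zero. Returns frame-averaged chroma.
    """
    freqs = spec.bin_freqs_hz
    audible = freqs >= 30.0
    pitch_class = np.zeros(len(freqs), dtype=int)
    pitch_class[audible] = (
        np.round(12 * np.log2(freqs[audible] / 440.0)).astype(int) + 9
    ) % n_chroma
    energy = spec.magnitudes**2
    per_frame = np.zeros((n_chroma, energy.shape[1]))
    for pc in range(n_chroma):
        mask = audible & (pitch_class == pc)
        per_frame[pc] = energy[mask].sum(axis=0)
    totals = per_frame.sum(axis=0)
    nz = totals > 0
    per_frame[:, nz] /= totals[nz]
    return per_frame.mean(axis=1)


# basis of the 6-D tonal-centroid (tonnetz) projection: fifths circle,
# minor-thirds circle, major-thirds circle
def _tonnetz_basis(n_chroma: int = 12) -> np.ndarray:
    pc = np.arange(n_chroma)
    return np.vstack(
        [
            np.sin(pc * 7 * np.pi / 6),
            np.cos(pc * 7 * np.pi / 6),
            np.sin(pc * 3 * np.pi / 2),
            np.cos(pc * 3 * np.pi / 2),
            0.5 * np.sin(pc * 2 * np.pi / 3),
            0.5 * np.cos(pc * 2 * np.pi / 3),
        ]
    )


def tonnetz(chroma_vec: np.ndarray) -> np.ndarray:
    """6-D harmonic-network projection of an (already normalized) chroma."""
    total = chroma_vec.sum()
    c = chroma_vec / total if total > 0 else chroma_vec
    return _tonnetz_basis(len(chroma_vec)) @ c


def spectral_contrast(
    spec: Spectrogram, sample_rate: int, n_bands: int = 6, alpha: float = 0.02
) -> np.ndarray:
    """Per-band peak-valley spread of the log spectrum, frame-averaged.

    Octave bands start at 200 Hz; within each band and frame the contrast
    is ``log(mean of top alpha-fraction) - log(mean of bottom
    alpha-fraction)`` of the magnitudes. Returns ``n_bands + 1`` values
    (including the sub-200 Hz band).
    """
    edges = [0.0] + [200.0 * 2**k for k in range(n_bands)] + [sample_rate / 2]
    freqs = spec.bin_freqs_hz
    mags = spec.magnitudes
    out = np.zeros(n_bands + 1)
    for b in range(n_bands + 1):
        mask = (freqs >= edges[b]) & (freqs < edges[b + 1])
        if not mask.any():
            continue
        band = np.sort(mags[mask], axis=0)  # (band_bins, frames)
        k = max(1, int(round(alpha * band.shape[0])))
        valley = np.log(band[:k].mean(axis=0) + _EPS)
        peak = np.log(band[-k:].mean(axis=0) + _EPS)
        out[b] = (peak - valley).mean()
    return out


# ---------------------------------------------------------------------------
# feature vectors


def _finalize(names: list[str], values: list[float]) -> FeatureVector:
    arr = np.asarray(values, dtype=np.float64)
    bad = ~np.isfinite(arr)
    if bad.any():
        warnings.warn(
            f"imputing {int(bad.sum())} non-finite feature value(s) to 0",
            stacklevel=3,
        )
        arr[bad] = 0.0
    return FeatureVector(names=tuple(names), values=arr)


def base_features(
    segment: AudioClip, config: FeatureConfig = FeatureConfig()
) -> FeatureVector:
    """Base feature vector (spectrogram stats + ZCR/centroid/MFCC + time stats)."""
    x = segment.samples
    spec = stft_spectrogram(segment, config.window_len, config.hop, config.pad_to)
    mags = spec.magnitudes

    names: list[str] = []
    values: list[float] = []

    for stat_name, stat in (
        ("mean", mags.mean(axis=1)),
        ("std", mags.std(axis=1)),
        ("max", mags.max(axis=1)),
    ):
        names += [f"bin{stat_name}_{i:03d}" for i in range(mags.shape[0])]
        values += list(stat)

    # frequency of maximum energy over the whole spectrogram
    bin_energy = (mags**2).sum(axis=1)
    argmax_hz = spec.bin_freqs_hz[int(np.argmax(bin_energy))] if bin_energy.any() else 0.0
    names.append("argmax_energy_hz")
    values.append(float(argmax_hz))

    names.append("zcr")
    values.append(zero_crossing_rate(x))
    names.append("spectral_centroid_hz")
    values.append(spectral_centroid(spec))

    for i, c in enumerate(mfcc(spec, segment.sample_rate, config.n_mfcc, config.n_mels)):
        names.append(f"mfcc_{i:02d}")
        values.append(float(c))

    names += ["time_mean", "time_std"]
    values += [float(x.mean()), float(x.std())]

    for w, chunk in enumerate(np.array_split(x, config.n_time_windows)):
        names += [f"win{w:02d}_{s}" for s in ("min", "max", "mean", "std")]
        values += [
            float(chunk.min()),
            float(chunk.max()),
            float(chunk.mean()),
            float(chunk.std()),
        ]

    return _finalize(names, values)


def extended_features(
    segment: AudioClip, config: FeatureConfig = FeatureConfig()
) -> FeatureVector:
    """Base features plus tonnetz, spectral contrast and chroma blocks."""
    base = base_features(segment, config)
    spec = stft_spectrogram(
        segment, config.harmonic_window_len, config.harmonic_hop, config.harmonic_pad_to
    )

    names = list(base.names)
    values = list(base.values)

    chroma_vec = chroma(spec, config.n_chroma)
    for i, v in enumerate(tonnetz(chroma_vec)):
        names.append(f"tonnetz_{i}")
        values.append(float(v))
    for i, v in enumerate(
        spectral_contrast(spec, segment.sample_rate, config.n_contrast_bands)
    ):
        names.append(f"contrast_{i}")
        values.append(float(v))
    for i, v in enumerate(chroma_vec):
        names.append(f"chroma_{i:02d}")
        values.append(float(v))

    return _finalize(names, values)


def n_base_features(config: FeatureConfig = FeatureConfig()) -> int:
    """Length of the base feature vector for ``config``."""
    n_bins = config.pad_to // 2 + 1
    return 3 * n_bins + 3 + config.n_mfcc + 2 + 4 * config.n_time_windows


def feature_matrix(
    clips: list[AudioClip],
    config: FeatureConfig = FeatureConfig(),
    extended: bool = True,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Stack feature vectors for many clips into ``(X, names)``.

    The extended vector is a superset of the base vector (the first
    ``n_base_features(config)`` columns), so one extended matrix serves
    both classifiers.
    """
    extractor = extended_features if extended else base_features
    vectors = [extractor(c, config) for c in clips]
    return np.vstack([v.values for v in vectors]), vectors[0].names


# ---------------------------------------------------------------------------
# ANOVA-F selection


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of top-k ANOVA-F feature selection."""

    indices: np.ndarray  # selected feature indices, ascending
    f_statistics: np.ndarray = field(repr=False)
    k: int


def anova_f_select(
    features_matrix: np.ndarray, labels: np.ndarray, k: int
) -> SelectionResult:
    """Select the ``k`` features with the largest one-way ANOVA F statistic.

    F = MS_between / MS_within per feature. Features with zero variance
    everywhere get F = 0; ties break toward the lower feature index. If
    ``k`` exceeds the number of features it is capped with a warning.
    """
    X = np.asarray(features_matrix, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features_matrix must be 2-D")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 classes with >= 2 samples each")
    if k > X.shape[1]:
        warnings.warn(f"k={k} > n_features={X.shape[1]}; capping", stacklevel=2)
        k = X.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features yield 0/0
        f_stats, _ = f_classif(X, y)
    f_stats = np.nan_to_num(f_stats, nan=0.0, posinf=np.inf)
    order = np.argsort(-f_stats, kind="stable")[:k]  # stable: ties -> lower index
    return SelectionResult(
        indices=np.sort(order), f_statistics=f_stats, k=k
    )


class AnovaKBest(BaseEstimator, TransformerMixin):
    """sklearn transformer wrapping :func:`anova_f_select` for pipelines."""

    def __init__(self, k: int = 150):
        self.k = k

    def fit(self, X, y):
        self.result_ = anova_f_select(np.asarray(X), np.asarray(y), self.k)
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.result_.indices]
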