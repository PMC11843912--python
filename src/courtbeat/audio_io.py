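"""WAV reading/writing with RIFF-convention amplitude normalization.

All downstream analysis runs on mono signals whose samples lie in
``[-1, 1]`` (integer PCM divided by the type maximum, the convention used
by the RIFF/WAV container). Stereo input is mixed to mono by the channel
mean. Resampling is never performed implicitly: operations that require a
specific rate assert it, because silent resampling would shift peak times.
"""

from __future__ import annotations

import logging
import wave
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io.wavfile

logger = logging.getLogger(__name__)

#: scale factor applied when normalizing integer PCM of each width
_PCM_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


class AudioFormatError(ValueError):
    """Raised when a WAV file cannot be read or uses an unsupported encoding."""


@dataclass(frozen=True)
class AudioClip:
    """A mono audio signal with normalized amplitudes.

    Parameters
    ----------
    samples
        1-D float array of amplitudes in ``[-1, 1]``.
    sample_rate
        Sampling rate in Hz (positive integer).
    """

    samples: np.ndarray = field(repr=False)
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioClip samples must be 1-D (mono)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        """Duration in seconds."""
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(len(self.samples)) / self.sample_rate


def normalize(samples: np.ndarray) -> np.ndarray:
    """Scale ``samples`` into ``[-1, 1]`` if any exceed unit amplitude.

    Idempotent: a signal already inside the unit interval is returned
    unchanged (no rescaling to full scale).
    """
    samples = np.asarray(samples, dtype=np.float64)
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak > 1.0:
        samples = samples / peak
    return samples


def _read_wav_24bit(path: Path) -> tuple[int, np.ndarray]:
    with wave.open(str(path), "rb") as w:
        if w.getsampwidth() != 3:
            raise AudioFormatError(f"{path}: not 24-bit PCM")
        n_channels = w.getnchannels()
        rate = w.getframerate()
        raw = w.readframes(w.getnframes())
    data = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
    # sign-extend 3 little-endian bytes into int32, then scale as 24-bit
    padded = np.zeros((data.shape[0], 4), dtype=np.uint8)
    padded[:, 1:] = data
    values = padded.view("<i4").ravel()  # 24-bit value shifted left by 8
    samples = values.astype(np.float64) / 2**31
    if n_channels > 1:
        samples = samples.reshape(-1, n_channels)
    return rate, samples


def read_wav(path: str | Path) -> AudioClip:
    """Read a PCM or float WAV file into a normalized mono :class:`AudioClip`.

    Integer PCM is divided by the type maximum (e.g. ``2**15`` for 16-bit);
    stereo is mixed to mono by the arithmetic channel mean.

    Raises
    ------
    AudioFormatError
        If the file is unreadable, truncated, or uses an unsupported
        encoding (e.g. compressed WAV).
    """
    path = Path(path)
    if not path.is_file():
        raise AudioFormatError(f"no such WAV file: {path}")
    try:
        rate, data = scipy.io.wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc

    data = np.atleast_1d(data)
    dtype = data.dtype
    if dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[dtype]
    elif dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV sample type {dtype} in {path}")

    if samples.ndim == 2:  # stereo (or more): mean mixdown
        samples = samples.mean(axis=1)
    return AudioClip(samples=normalize(samples), sample_rate=int(rate))


def _write_wav_24bit(path: Path, rate: int, samples: np.ndarray) -> None:
    scaled = np.round(samples * (2**23 - 1)).astype("<i4")
    raw = scaled.view(np.uint8).reshape(-1, 4)[:, :3].tobytes()
    with wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(3)
        w.setframerate(rate)
        w.writeframes(raw)


def write_wav(clip: AudioClip, path: str | Path, bit_depth: str | int = 16) -> None:
    """Write ``clip`` to a standard WAV container.

    Parameters
    ----------
    clip
        The audio to write.
    path
        Destination file path.
    bit_depth
        One of ``16``, ``24`` (integer PCM) or ``"float32"``.

    Samples outside ``[-1, 1]`` are saturated, with a logged warning.
    """
    path = Path(path)
    samples = clip.samples
    n_clipped = int(np.sum(np.abs(samples) > 1.0))
    if n_clipped:
        logger.warning("write_wav: saturating %d samples outside [-1, 1]", n_clipped)
        samples = np.clip(samples, -1.0, 1.0)

    if bit_depth in (16, "16"):
        scipy.io.wavfile.write(
            path, clip.sample_rate, np.round(samples * (2**15 - 1)).astype(np.int16)
        )
    elif bit_depth in (24, "24"):
        _write_wav_24bit(path, clip.sample_rate, samples)
    elif bit_depth == "float32":
        scipy.io.wavfile.write(path, clip.sample_rate, samples.astype(np.float32))
    else:
        raise ValueError(f"bit_depth must be 16, 24 or 'float32', got {bit_depth!r}")
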