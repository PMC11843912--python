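"""Synthetic court-audio generator: sounds, scenes, and labeled banks.

Emulates the three sound classes of on-court audio:

* **impact** — the ball striking the string bed: a sharp, 20-50 ms burst
  dominated by high-frequency energy (damped sinusoids in 600-4000 Hz
  plus a band-limited noise burst), with a weaker low-frequency body
  component so the impact also survives 100-400 Hz band-pass filtering,
  as real impacts do.
* **rebound** — the ball bouncing on the court: a 50-150 ms damped
  oscillation with dominant energy inside 100-400 Hz, typically much
  quieter than an impact.
* **noise** — ambient textures (wind, voices, traffic, crowd) and
  transient non-ball sounds (voice bursts, gusts, metallic clanks).

Scenes mix events additively over ambient noise at known times and
return exact ground truth; banks provide labeled 0.3 s clips for
classifier training. Every generator is a pure function of its seed.

Synthesis recipes (component frequencies, decay constants, SNR ranges,
far-player attenuation) are this package's own choices, made to match
the qualitative acoustic signatures above; all are exposed as
parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal

from courtbeat.audio_io import AudioClip, write_wav, read_wav
from courtbeat.events import IMPACT, NOISE, REBOUND, EventRecord, write_events_csv

logger = logging.getLogger(__name__)

NOISE_KINDS = ("wind", "voice", "traffic", "crowd")
TRANSIENT_KINDS = ("voice_burst", "gust", "clank")


@dataclass(frozen=True)
class EventSpec:
    """One event to inject into a scene."""

    time_s: float
    kind: str  # impact | rebound | noise
    amplitude: float
    player: str = "near"  # near | far | none

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError("time_s must be >= 0")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must be in (0, 1]")
        if self.kind not in (IMPACT, REBOUND, NOISE):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.player not in ("near", "far", "none"):
            raise ValueError(f"unknown player {self.player!r}")


@dataclass(frozen=True)
class SceneSpec:
    """A full court-audio scene: events over an ambient bed."""

    duration_s: float
    events: tuple[EventSpec, ...] = ()
    ambient_kind: str = "wind"
    ambient_snr_db: float = 20.0  # peak event amplitude vs ambient RMS
    seed: int = 0
    sample_rate: int = 48000
    far_attenuation: float = 0.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        for e in self.events:
            if e.time_s >= self.duration_s:
                raise ValueError("all event times must be < duration_s")


@dataclass(frozen=True)
class BankSpec:
    """Labeled training-bank composition.

    Default class counts (509 noise / 442 rebound / 448 impact) define
    the standard 1399-clip bank used for classifier training and
    cross-validation.
    """

    n_noise: int = 509
    n_rebound: int = 442
    n_impact: int = 448
    clip_length_s: float = 0.3
    sample_rate: int = 48000
    seed: int = 42
    snr_db_range: tuple[float, float] = (5.0, 25.0)
    overlap_fraction: float = 0.2  # events with a coinciding noise transient

    def __post_init__(self) -> None:
        if min(self.n_noise, self.n_rebound, self.n_impact) < 0:
            raise ValueError("class counts must be >= 0")


# ---------------------------------------------------------------------------
# elementary sounds


def _attack_envelope(n: int, sample_rate: int, attack_s: float) -> np.ndarray:
    """Raised-cosine attack so the waveform peak is an interior sample."""
    env = np.ones(n)
    na = max(2, int(attack_s * sample_rate))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(min(na, n)) / na))
    env[: len(ramp)] = ramp
    return env


def _peak_scale(x: np.ndarray, amplitude: float) -> np.ndarray:
    peak = np.max(np.abs(x))
    if peak == 0:
        return x
    return x * (amplitude / peak)


def gen_impact(
    sample_rate: int = 48000,
    amplitude: float = 0.8,
    seed: int = 0,
    duration_s: float = 0.03,
) -> AudioClip:
    """A string-bed impact: sharp high-frequency burst, peak == amplitude."""
    if not 0 < amplitude <= 1:
        raise ValueError("amplitude must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = int(duration_s * sample_rate)
    t = np.arange(n) / sample_rate
    hf = np.zeros(n)
    # 4 damped high-frequency partials (string/ball vibration)
    for _ in range(4):
        f = rng.uniform(600.0, 4000.0)
        tau = rng.uniform(0.006, 0.012)
        a = rng.uniform(0.8, 1.3)
        hf += a * np.exp(-t / tau) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    # broadband burst, high-passed above 500 Hz
    sos = scipy.signal.butter(4, 500.0, btype="highpass", fs=sample_rate, output="sos")
    burst = scipy.signal.sosfilt(sos, rng.standard_normal(n))
    hf += 0.6 * np.exp(-t / 0.004) * burst / (np.max(np.abs(burst)) + 1e-12)
    hf /= np.max(np.abs(hf)) + 1e-12
    # weaker low-frequency body thump, at a fixed ratio to the burst peak,
    # keeps the impact visible after 100-400 Hz band-pass, as in real
    # recordings
    f_lo = rng.uniform(200.0, 300.0)
    x = hf + 0.55 * np.exp(-t / 0.006) * np.sin(2 * np.pi * f_lo * t)
    x *= _attack_envelope(n, sample_rate, 0.001)
    return AudioClip(samples=_peak_scale(x, amplitude), sample_rate=sample_rate)


def gen_rebound(
    sample_rate: int = 48000,
    amplitude: float = 0.15,
    seed: int = 0,
    duration_s: float = 0.1,
) -> AudioClip:
    """A ground-rebound thump: damped 100-400 Hz oscillation, peak == amplitude."""
    if not 0 < amplitude <= 1:
        raise ValueError("amplitude must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = int(duration_s * sample_rate)
    t = np.arange(n) / sample_rate
    f0 = rng.uniform(140.0, 250.0)
    f1 = min(1.6 * f0, 390.0)
    x = np.exp(-t / rng.uniform(0.02, 0.04)) * np.sin(2 * np.pi * f0 * t)
    x += 0.5 * np.exp(-t / rng.uniform(0.015, 0.03)) * np.sin(
        2 * np.pi * f1 * t + rng.uniform(0, 2 * np.pi)
    )
    # faint in-band noise for texture
    sos = scipy.signal.butter(
        4, [100.0, 400.0], btype="bandpass", fs=sample_rate, output="sos"
    )
    tex = scipy.signal.sosfilt(sos, rng.standard_normal(n))
    x += 0.1 * np.exp(-t / 0.03) * tex / (np.max(np.abs(tex)) + 1e-12)
    x *= _attack_envelope(n, sample_rate, 0.002)
    return AudioClip(samples=_peak_scale(x, amplitude), sample_rate=sample_rate)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-shaped Gaussian noise via spectral shaping."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    shaping[0] = 0.0
    return np.fft.irfft(spectrum * shaping, n=n)


def gen_noise(
    sample_rate: int = 48000,
    kind: str = "wind",
    amplitude: float = 0.1,
    duration_s: float = 1.0,
    seed: int = 0,
) -> AudioClip:
    """Ambient noise of the given kind; peak |sample| <= amplitude.

    * ``wind`` — low-pass-filtered 1/f noise with slow amplitude modulation
    * ``voice`` — mid-band modulated harmonics with a randomized pitch contour
    * ``traffic`` / ``crowd`` — broadband colored noise
    """
    if kind not in NOISE_KINDS:
        raise ValueError(f"kind must be one of {NOISE_KINDS}, got {kind!r}")
    rng = np.random.default_rng(seed)
    n = int(duration_s * sample_rate)
    t = np.arange(n) / sample_rate

    if kind == "wind":
        # wind rumble: red-ish spectrum, mostly below a few hundred Hz
        x = np.cumsum(rng.standard_normal(n))
        x -= np.linspace(x[0], x[-1], n)  # detrend the random walk
        sos = scipy.signal.butter(4, 300.0, btype="lowpass", fs=sample_rate, output="sos")
        x = scipy.signal.sosfilt(sos, x)
        mod = 0.6 + 0.4 * np.sin(2 * np.pi * rng.uniform(0.1, 0.6) * t + rng.uniform(0, 2 * np.pi))
        x *= mod
    elif kind == "voice":
        # pitch contour wandering around 100-250 Hz, harmonics to ~1 kHz
        f0 = rng.uniform(110.0, 220.0)
        contour = f0 * (1 + 0.1 * np.cumsum(rng.standard_normal(n)) / np.sqrt(n))
        phase = 2 * np.pi * np.cumsum(contour) / sample_rate
        x = np.zeros(n)
        for h in range(1, 6):
            if h * f0 > 1000:
                break
            x += np.sin(h * phase + rng.uniform(0, 2 * np.pi)) / h
        syllabic = 0.5 + 0.5 * np.abs(np.sin(2 * np.pi * rng.uniform(2.0, 5.0) * t))
        x *= syllabic
    elif kind == "traffic":
        x = _pink_noise(rng, n)
        sos = scipy.signal.butter(4, 800.0, btype="lowpass", fs=sample_rate, output="sos")
        x = scipy.signal.sosfilt(sos, x)
    else:  # crowd
        x = _pink_noise(rng, n)
        mod = 0.7 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.5, 2.0) * t)
        x *= mod

    return AudioClip(samples=_peak_scale(x, amplitude), sample_rate=sample_rate)


def gen_transient_noise(
    sample_rate: int = 48000,
    kind: str = "voice_burst",
    amplitude: float = 0.2,
    seed: int = 0,
) -> AudioClip:
    """A short non-ball transient (shout fragment, wind gust, metallic clank)."""
    if kind not in TRANSIENT_KINDS:
        raise ValueError(f"kind must be one of {TRANSIENT_KINDS}, got {kind!r}")
    rng = np.random.default_rng(seed)
    if kind == "voice_burst":
        clip = gen_noise(sample_rate, "voice", 1.0, rng.uniform(0.12, 0.25), seed)
        x = clip.samples * _attack_envelope(len(clip.samples), sample_rate, 0.02)
    elif kind == "gust":
        clip = gen_noise(sample_rate, "wind", 1.0, rng.uniform(0.2, 0.4), seed)
        n = len(clip.samples)
        bump = np.hanning(n)
        x = clip.samples * bump
    else:  # clank: pitched metallic ring, slow decay, mid-high frequency
        n = int(rng.uniform(0.08, 0.15) * sample_rate)
        t = np.arange(n) / sample_rate
        x = np.zeros(n)
        f = rng.uniform(700.0, 2500.0)
        for mult in (1.0, 2.76, 5.40):  # bar-like inharmonic partials
            x += np.exp(-t / rng.uniform(0.03, 0.06)) * np.sin(
                2 * np.pi * f * mult * t + rng.uniform(0, 2 * np.pi)
            ) / mult
        x *= _attack_envelope(n, sample_rate, 0.002)
    return AudioClip(samples=_peak_scale(x, amplitude), sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# scenes


def _event_clip(kind: str, sample_rate: int, amplitude: float, seed: int) -> AudioClip:
    if kind == IMPACT:
        return gen_impact(sample_rate, amplitude, seed)
    if kind == REBOUND:
        return gen_rebound(sample_rate, amplitude, seed)
    rng = np.random.default_rng(seed)
    t_kind = TRANSIENT_KINDS[rng.integers(len(TRANSIENT_KINDS))]
    return gen_transient_noise(sample_rate, t_kind, amplitude, seed + 1)


def render_scene(spec: SceneSpec) -> tuple[AudioClip, list[EventRecord]]:
    """Mix a scene and return ``(clip, ground_truth)``.

    Events are placed so the waveform peak of each injected sound falls
    exactly at its annotated time; far-player events are attenuated by
    ``spec.far_attenuation``. The ambient bed is scaled so that the
    loudest event's peak amplitude sits ``ambient_snr_db`` above the
    ambient RMS. Identical-time events are summed (logged). The mix is
    saturated at +/-1 if the sum exceeds full scale.
    """
    sr = spec.sample_rate
    n = int(spec.duration_s * sr)
    seq = np.random.SeedSequence(spec.seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in seq.spawn(len(spec.events) + 1)]

    ref_amp = 1.0
    amps = [
        e.amplitude * (spec.far_attenuation if e.player == "far" else 1.0)
        for e in spec.events
    ]
    if amps:
        ref_amp = max(amps)
    ambient = gen_noise(sr, spec.ambient_kind, 1.0, spec.duration_s, child_seeds[0])
    ambient_rms = np.sqrt(np.mean(ambient.samples**2)) + 1e-12
    target_rms = ref_amp * 10 ** (-spec.ambient_snr_db / 20)
    mix = ambient.samples * (target_rms / ambient_rms)

    truth: list[EventRecord] = []
    seen_times: set[float] = set()
    for e, amp, child in zip(spec.events, amps, child_seeds[1:]):
        if e.time_s in seen_times:
            logger.info("render_scene: summing overlapping events at t=%.3f s", e.time_s)
        seen_times.add(e.time_s)
        clip = _event_clip(e.kind, sr, amp, child)
        peak_idx = int(np.argmax(np.abs(clip.samples)))
        pos = int(round(e.time_s * sr)) - peak_idx
        lo, hi = max(pos, 0), min(pos + len(clip.samples), n)
        if hi > lo:
            mix[lo:hi] += clip.samples[lo - pos : hi - pos]
        truth.append(
            EventRecord(
                time_s=int(round(e.time_s * sr)) / sr,
                label=e.kind,
                amplitude=amp,
                probability=1.0,
            )
        )
    mix = np.clip(mix, -1.0, 1.0)
    return AudioClip(samples=mix, sample_rate=sr), sorted(truth, key=lambda r: r.time_s)


# ---------------------------------------------------------------------------
# labeled bank


def gen_sample_bank(spec: BankSpec = BankSpec()) -> tuple[list[AudioClip], list[str]]:
    """Generate the labeled training bank: ``(clips, labels)``, aligned.

    Impact and rebound clips contain a single event at a jittered onset
    over ambient noise at a randomized SNR (event peak vs ambient RMS,
    uniform over ``spec.snr_db_range``); a fraction
    ``spec.overlap_fraction`` also carry a coinciding noise transient.
    Noise clips contain ambient texture and, usually, a non-ball
    transient. Deterministic for a given spec.
    """
    sr = spec.sample_rate
    n = int(spec.clip_length_s * sr)
    counts = [(NOISE, spec.n_noise), (REBOUND, spec.n_rebound), (IMPACT, spec.n_impact)]
    total = sum(c for _, c in counts)
    seq = np.random.SeedSequence(spec.seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in seq.spawn(total)]

    clips: list[AudioClip] = []
    labels: list[str] = []
    i = 0
    for label, count in counts:
        for _ in range(count):
            seed = child_seeds[i]
            i += 1
            rng = np.random.default_rng(seed)
            ambient_kind = NOISE_KINDS[rng.integers(len(NOISE_KINDS))]
            ambient = gen_noise(sr, ambient_kind, 1.0, spec.clip_length_s, seed + 1)
            rms = np.sqrt(np.mean(ambient.samples**2)) + 1e-12

            if label == NOISE:
                amb_amp = rng.uniform(0.02, 0.25)
                x = ambient.samples / (np.max(np.abs(ambient.samples)) + 1e-12) * amb_amp
                if rng.random() < 0.7:  # usually a transient non-ball sound
                    t_kind = TRANSIENT_KINDS[rng.integers(len(TRANSIENT_KINDS))]
                    tr = gen_transient_noise(sr, t_kind, rng.uniform(0.05, 0.5), seed + 2)
                    onset = rng.integers(0, max(1, n - len(tr.samples)))
                    x = x.copy()
                    seg = tr.samples[: n - onset]
                    x[onset : onset + len(seg)] += seg
            else:
                if label == IMPACT:
                    amp = rng.uniform(0.4, 1.0)
                    event = gen_impact(sr, amp, seed + 2)
                else:
                    amp = rng.uniform(0.03, 0.12)
                    event = gen_rebound(sr, amp, seed + 2)
                snr = rng.uniform(*spec.snr_db_range)
                x = ambient.samples * (amp * 10 ** (-snr / 20) / rms)
                peak_idx = int(np.argmax(np.abs(event.samples)))
                onset_t = rng.uniform(0.08, spec.clip_length_s - 0.08)
                pos = int(onset_t * sr) - peak_idx
                lo, hi = max(pos, 0), min(pos + len(event.samples), n)
                x = x.copy()
                x[lo:hi] += event.samples[lo - pos : hi - pos]
                if rng.random() < spec.overlap_fraction:
                    t_kind = TRANSIENT_KINDS[rng.integers(len(TRANSIENT_KINDS))]
                    tr = gen_transient_noise(
                        sr, t_kind, amp * 10 ** (-snr / 20) * 2, seed + 3
                    )
                    t_pos = max(0, min(pos, n - len(tr.samples)))
                    seg = tr.samples[: n - t_pos]
                    x[t_pos : t_pos + len(seg)] += seg

            clips.append(AudioClip(samples=np.clip(x, -1, 1), sample_rate=sr))
            labels.append(label)
    return clips, labels


def save_bank(clips: list[AudioClip], labels: list[str], out_dir: str | Path) -> None:
    """Write a bank as WAV files plus ``labels.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (clip, label) in enumerate(zip(clips, labels)):
        name = f"clip_{i:05d}.wav"
        write_wav(clip, out_dir / name, bit_depth="float32")
        rows.append((name, label))
    pd.DataFrame(rows, columns=["file", "label"]).to_csv(
        out_dir / "labels.csv", index=False
    )


def load_bank(bank_dir: str | Path) -> tuple[list[AudioClip], list[str]]:
    """Read a bank directory written by :func:`save_bank`."""
    bank_dir = Path(bank_dir)
    table = pd.read_csv(bank_dir / "labels.csv")
    clips = [read_wav(bank_dir / f) for f in table["file"]]
    return clips, [str(x) for x in table["label"]]


def save_scene(
    clip: AudioClip, truth: list[EventRecord], wav_path: str | Path, csv_path: str | Path
) -> None:
    """Write a rendered scene as WAV plus ground-truth CSV."""
    write_wav(clip, wav_path, bit_depth="float32")
    write_events_csv(truth, csv_path)


# ---------------------------------------------------------------------------
# presets mirroring the validation scenarios


def rally_scene_spec(
    n_near: int = 8,
    span_s: float = 23.03,
    seed: int = 0,
    ambient_kind: str = "wind",
    ambient_snr_db: float = 30.0,
) -> SceneSpec:
    """A baseline-rally scene: ``n_near`` near-player impacts evenly
    spanning ``span_s`` seconds, with ``n_near - 1`` attenuated far-player
    impacts at the midpoints (one opponent shot inside each same-player
    interval)."""
    t0 = 1.0
    near_times = t0 + np.linspace(0.0, span_s, n_near)
    events = [EventSpec(float(t), IMPACT, 0.8, "near") for t in near_times]
    mid = (near_times[:-1] + near_times[1:]) / 2
    events += [EventSpec(float(t), IMPACT, 0.8, "far") for t in mid]
    return SceneSpec(
        duration_s=float(near_times[-1] + 1.5),
        events=tuple(sorted(events, key=lambda e: e.time_s)),
        ambient_kind=ambient_kind,
        ambient_snr_db=ambient_snr_db,
        seed=seed,
    )


def groundstroke_scene_spec(
    n_strokes: int = 20,
    timing_median_s: float = 0.81,
    timing_spread_s: float = 0.07,
    period_s: float = 3.0,
    seed: int = 0,
    ambient_kind: str = "wind",
    ambient_snr_db: float = 25.0,
) -> SceneSpec:
    """A groundstroke drill: each stroke is a rebound followed, after the
    executive timing, by the impact. Timings are drawn around
    ``timing_median_s`` (clipped to the 0.4-1.5 s rebound window)."""
    rng = np.random.default_rng(seed)
    events: list[EventSpec] = []
    for k in range(n_strokes):
        t_imp = 2.0 + k * period_s
        timing = float(
            np.clip(rng.normal(timing_median_s, timing_spread_s / 1.35), 0.45, 1.45)
        )
        events.append(EventSpec(t_imp - timing, REBOUND, float(rng.uniform(0.03, 0.08)), "near"))
        events.append(EventSpec(t_imp, IMPACT, float(rng.uniform(0.5, 0.9)), "near"))
    return SceneSpec(
        duration_s=2.0 + n_strokes * period_s,
        events=tuple(events),
        ambient_kind=ambient_kind,
        ambient_snr_db=ambient_snr_db,
        seed=seed,
    )


SCENE_PRESETS = {
    "rally1": lambda seed=0: rally_scene_spec(8, 23.03, seed),
    "rally2": lambda seed=0: rally_scene_spec(7, 18.29, seed),
    "g1": lambda seed=0: groundstroke_scene_spec(20, 0.81, 0.07, seed=seed),
    "g2": lambda seed=0: groundstroke_scene_spec(20, 0.56, 0.06, seed=seed),
}
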