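# Methods

This note documents the detection model, every tunable parameter and its
default, what the synthetic audio generator does and does not emulate,
and the numerical choices that affect results.

## 1. Measurement model

Two timing measures are extracted from single-microphone court audio.

**Rally rhythm.** During a baseline rally only the near player's string
impacts are reliably loud; the opponent's shots are attenuated by
distance. Exactly one opponent shot falls between two consecutive
near-player impacts, so an interval of Δt seconds corresponds to an
instantaneous frequency of 120/Δt shots/min, and n detected impacts
imply 2n − 1 total rally shots. The average frequency is
(2n − 1)/span × 60 over the first-to-last-impact span. A single-player
convention (60/Δt, n shots) is available via
`rally_rhythm(..., per_rally_shot=False)`.

**Groundstroke executive timing.** For each validated impact, the ball's
ground rebound is sought in the closed window [t − 1.5 s, t − 0.4 s]
before the impact; the executive timing is the difference
impact − rebound. The window bounds encode the plausible range of
bounce-to-hit intervals in rallying; anything closer than 0.4 s would be
a half-volley outside the measure's definition.

## 2. Detection pipeline

1. **Normalization** — samples scaled into [−1, 1] only if they exceed
   unit amplitude (integer PCM is divided by the type maximum on read).
2. **Rule-based peak picking** (module `peaks`):
   * Rally impacts: peaks of |x| on the *unfiltered* signal exceeding
     **0.4**, minimum separation **390 ms** (two rally shots by the same
     player cannot be closer).
   * Groundstroke candidates: on the band-passed signal, "lesser"
     candidates exceed **0.02** with **100 ms** separation; impact
     candidates are the lesser candidates exceeding **0.09** (so impacts
     are a subset of lesser candidates by construction). When two peaks
     violate the separation the larger survives (greedy by descending
     amplitude). All thresholds are strict ("exceeding").
3. **Band-pass filter** (module `dsp`): order-5 Butterworth band-pass
   **100–400 Hz**, applied zero-phase (forward–backward), so that peak
   times are not delayed; the effective magnitude response is squared.
   The band is where the rebound carries its energy; the impact's
   low-frequency body keeps it visible after filtering as well.
4. **Classifier validation** (module `models`): each candidate segment
   (50 ms before the peak to 250 ms after, zero-padded at clip edges)
   is classified; a candidate counts as a ball sound only when the
   positive-class probability **strictly exceeds 0.5** (ties go to
   noise). For each kept impact, the accepted rebound candidate with the
   highest probability wins, ties resolved toward the later time.

## 3. Features (module `features`)

Base set (impact model), from a Hann STFT with **320-sample windows,
160-sample hop, zero-padded to 512 points** at 48 kHz:

* per-bin mean/std/max of the magnitude spectrogram (3 × 257),
* frequency of maximum energy, zero-crossing rate, spectral centroid,
* 13 frame-averaged MFCCs (26 triangular mel filters, log power,
  orthonormal DCT-II),
* overall time mean/std and min/max/mean/std over 10 equal time windows.

Extended set (rebound ensemble) appends 6 tonnetz coordinates
(fifths/minor-thirds/major-thirds projection of chroma), 7 per-band
spectral contrast values (octave bands from 200 Hz; contrast is the log
ratio of the top to bottom 2% of magnitudes per band and frame), and 12
chroma bins (energy folded into pitch classes, normalized per frame).

**Harmonic-window choice.** The 320-sample detection window has ~150 Hz
frequency resolution — useless for pitch structure inside the 100–400 Hz
rebound band. The chroma/tonnetz/contrast blocks therefore use their own
STFT with **1024-sample windows, 512 hop, 2048-point padding**
(~23 Hz resolution). Without this the rebound ensemble cannot separate
rebounds from wind rumble.

Feature selection is a top-k one-way ANOVA F-test
(F = MS_between/MS_within per feature), embedded *inside* each model
pipeline so that cross-validation fits selection (and scaling) on
training folds only. **k defaults to 150**, chosen by a grid search over
{40, 80, 150, 250} using the package's own five-fold CV on the default
bank (rebound-ensemble median accuracy 0.947/0.958/0.968/0.963; the
impact model is insensitive, ≥ 0.99 throughout).

## 4. Classifiers

* **Impact vs. noise**: XGBoost, learning rate 0.1, 300 trees, max depth
  3, on the base features.
* **Rebound vs. noise**: soft-voting ensemble (arithmetic mean of member
  probabilities) of XGBoost (0.05, 500 trees, depth 5), an RBF SVM
  (C = 1, gamma = "scale", Platt-calibrated probabilities) and an MLP
  (one hidden layer of 100 ReLU units, Adam), on the extended features.
  The SVM and MLP members see z-scored features (scaler fit on training
  data only); tree members consume raw features.

Evaluation is stratified five-fold cross-validation (shuffled, seeded);
reported per model as per-fold accuracies and their median.

## 5. Synthetic audio (module `synthcourt`)

No recordings ship with the package; all audio is synthesized at 48 kHz
with exact ground truth. Recipes (frequencies, decay constants, SNR
ranges) are this package's own choices, made to reproduce the
qualitative acoustic signatures the detection rules rely on:

* **Impact**: four damped sinusoids in 600–4000 Hz plus a high-passed
  noise burst (normalized to unit peak), plus a weaker 200–300 Hz body
  component at 0.55 relative amplitude so the impact also survives the
  100–400 Hz band-pass; peak-scaled to the requested amplitude.
* **Rebound**: two damped partials with fundamental 140–250 Hz (second
  partial capped at 390 Hz), 15–40 ms decay, faint in-band noise
  texture; rebounds are synthesized much quieter than impacts
  (amplitudes 0.03–0.12 in banks), consistent with the 0.02/0.09
  thresholds that separate them.
* **Noise**: ambient textures — wind (detrended random-walk rumble,
  low-passed at 300 Hz, slow amplitude modulation), voice (pitch-contour
  harmonics to ~1 kHz with syllabic modulation), traffic and crowd
  (shaped pink noise) — plus transients (voice bursts, gusts, metallic
  clanks with inharmonic partials).

Scenes place events so the waveform peak lands exactly on the annotated
sample; the ambient bed is scaled so the loudest event's peak sits
`ambient_snr_db` above the ambient RMS; far-player impacts are
attenuated ×0.25 (below the 0.4 rally threshold). The default training
bank contains **509 noise / 442 rebound / 448 impact** clips of 0.3 s
(seed 42), with event SNR uniform in 5–25 dB and 20% of event clips
carrying a coinciding noise transient.

**Separability gate.** Any change to generator defaults must keep the
default bank learnable: the five-fold CV medians of both classifiers
must stay ≥ 0.95 (current values ≈ 0.995 impact, ≈ 0.968 rebound).

What is *not* emulated: room/court reverberation, microphone directivity
and clipping, Doppler, footstep and racket-frame sounds, multiple
simultaneous courts. Conclusions about absolute on-court detection rates
therefore do not transfer; the synthetic data exists to verify the
pipeline's mechanics and relative behavior.

## 6. Agreement statistics (module `agreement`)

Detections are matched one-to-one to reference events greedily by
smallest absolute time difference within **20 ms** (five times the 4 ms
frame error of a 240 fps video reference). Detection rate is
100·TP/(TP+FN). Paired timings are compared with:

* **CV% (RMS method)**: 100·sqrt(mean(dᵢ²/2mᵢ²)) over pairs (zero-mean
  pairs excluded with a warning);
* **ICC(3,1)** from two-way mean squares, CI by the classical F-bound
  construction (degenerate data: NaN for zero subject variance, CI (1,1)
  for perfect agreement);
* **weighted kappa** (quadratic weights, statsmodels) after binning both
  series into common **0.04 s** bins, with its standard error;
* **Spearman's rho**, **Mann-Whitney U** (exact for tie-free n ≤ 8,
  asymptotic otherwise), and **Bland-Altman** limits of agreement
  (±1.96 SD; CI of each limit via SE = SD·sqrt(3/n)).

## 7. Numerical and reproducibility choices

* All randomness flows from `numpy.random.SeedSequence` spawning; every
  command honors `--seed`, and identical config + seed reproduce
  bit-identical CSVs.
* WAV I/O: 16/24-bit integer PCM and float32; integer samples divided by
  the type maximum (RIFF convention); stereo mixed by channel mean; no
  implicit resampling.
* Quantiles (median/IQR) use linear interpolation (`numpy.quantile`
  default).
* Problem sizes in the test suite (560-clip fixture bank, 10-stroke
  scenes) are the package's own choices balancing coverage against the
  test-time budget; the full 1399-clip default bank is exercised by the
  cross-validation acceptance test and `scripts/acceptance.py`.

## 8. Known limitations

* The rebound ensemble's recall degrades at low SNR (quiet rebounds
  under wind); on clean scenes recovery is complete to within ±10 ms,
  which is what the end-to-end tests assert.
* Rally rhythm assumes strict near/far alternation; tiebreak patterns or
  missed shots violate the 2n − 1 inference.
* The ICC/kappa implementations assume two raters (system vs.
  reference); multi-rater designs are out of scope.
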