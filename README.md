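# courtbeat

Acoustic detection of tennis ball sounds for timing assessment. From a
single microphone recording of court audio, courtbeat finds the two ball
sounds that matter for stroke timing — the **impact** on the string bed
and the preceding **ground rebound** — and turns them into two
behavioural measures:

* **Rally rhythm** (shots per minute) during baseline rallies. Only the
  near player's impacts are loud enough to detect, and exactly one
  opponent shot falls inside each same-player interval, so an interval of
  Δt seconds corresponds to 120/Δt shots/min and n detected impacts imply
  2n − 1 total rally shots.
* **Groundstroke executive timing**: the interval from the ball's bounce
  to its impact on the strings (rebound sought 0.4–1.5 s before each
  impact), a measure of how late or early a player times the stroke.

Candidate peaks are found by simple amplitude/interval rules, then
validated by two trained classifiers — a gradient-boosted tree model for
impact vs. noise and a soft-voting ensemble (boosted trees + RBF SVM +
MLP) for rebound vs. noise — so that shouts, gusts and clanks are
rejected. Agreement with a reference annotation is quantified with the
standard inter-method statistics (ICC(3,1), weighted kappa, CV%,
Spearman's rho, Mann-Whitney, Bland-Altman).

Because no on-court recordings ship with the package, a synthetic
court-audio generator (`courtbeat.synthcourt`) produces impacts,
rebounds and realistic noise textures with exact ground truth; it is
used for training banks, demos and the test suite. See
`docs/methods.md` for the full model and parameter rationale.

## Quick start

Render a synthetic rally scene and measure its rhythm:

```sh
courtbeat synth scene --preset rally1 --out demo --seed 0
courtbeat detect demo/rally1.wav --mode rally --out demo/rally
```

which prints:

```json
{
  "n_near_impacts": 8,
  "inferred_total_shots": 15,
  "span_s": 23.03,
  "average_freq_spm": 39.08,
  "instantaneous_freqs_spm": [36.47, 36.47, 36.47, 36.49, 36.47, 36.47, 36.47]
}
```

Train the classifiers and measure groundstroke timing:

```sh
courtbeat synth bank --out bank --seed 42          # 1399 labeled clips
courtbeat train bank --out model.joblib --seed 42  # both classifiers
courtbeat synth scene --preset g1 --out demo       # groundstroke drill
courtbeat evaluate demo/g1.wav demo/g1_truth.csv --model model.joblib --out demo/g1_out
```

`evaluate` writes `events.csv` (detected events), `timing_report.json`
(median/IQR executive timing) and `agreement.json` (per-label detection
rates plus the timing agreement statistics against the ground truth).

The same pipeline is available as a library:

```python
from courtbeat.audio_io import read_wav
from courtbeat.dsp import butter_bandpass
from courtbeat.models import ModelBundle, classify_events
from courtbeat.peaks import detect_groundstroke_candidates
from courtbeat import timing

clip = read_wav("demo/g1.wav")
impacts, lesser = detect_groundstroke_candidates(butter_bandpass(clip))
events = classify_events(clip, impacts, lesser, ModelBundle.load("model.joblib"))
summary = timing.summarize_timing(
    timing.executive_timing(timing.pair_impact_rebound(events))
)
print(summary.median_s, summary.iqr_s)
```

## Testing

```sh
python -m pytest -q
```

The suite covers WAV round-trips, filter/STFT invariants, a brute-force
peak-detection oracle (hypothesis), hand-computed statistics oracles
(with pingouin as an independent ICC check), model/CV bookkeeping, the
synthetic generator's acoustic signatures, CLI behaviour, and end-to-end
timing recovery within ±10 ms on clean scenes. `tests/test_acceptance.py`
holds one test per acceptance criterion; the cross-validation criterion
dominates the runtime (a few minutes).
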