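# triqrs

Low-complexity, streaming-capable **R-peak (QRS) detection** for
single-channel ECG, built entirely from moving-average filters and a
triangle template matched filter, with AAMI-style beat-by-beat evaluation
and a seedable synthetic-ECG generator.

## Who this is for

Locating the R peak of every heartbeat is the first step of almost all ECG
analysis (heart-rate, HRV, arrhythmia screening). Classic detectors
(Pan–Tompkins and descendants) rely on band-pass filter banks and
multi-stage adaptive thresholds; this package implements a deliberately
minimal alternative whose every stage is either a moving average or a
two-multiplication template, so it runs sample-by-sample with O(1) work per
sample and a fixed, sub-second initialisation latency — the kind of
detector one would put on a wearable or embedded front end, here as a
tested reference implementation with batch and streaming modes that agree
exactly.

## The method

Six stages, all windows derived from the sampling rate *f<sub>s</sub>*
(360 Hz working rate by default; other inputs are polyphase-resampled):

1. **High-pass** (baseline-wander / T-wave removal), a centered
   moving-average subtractor with rectification:
   ŷ(i) = x(i) − (2N+1)⁻¹ Σ<sub>j=−N</sub><sup>N</sup> x(i+j),  y(i) = |ŷ(i)|.
   N is the smallest half-window with f<sub>s</sub>/(2N+1) ≤ √2·f<sub>c</sub>
   (N = 25 at 360 Hz for f<sub>c</sub> = 5 Hz).
2. **Triangle template matching**, the product of the two slope segments
   across ±s samples, positive part retained:
   t(i) = max(0, (y(i) − y(i−s))(y(i) − y(i+s))), with
   s = ⌊0.020·f<sub>s</sub>⌋ (7 at 360 Hz; a 40 ms template well inside the
   80–120 ms QRS width). Apexes score ∝ slope², ramps and broadband noise
   score ≈ 0.
3. **Low-pass**, a centered moving mean of half-window L (smallest L with
   f<sub>s</sub>/(2L+1) ≤ 35 Hz; L = 5 at 360 Hz), giving l(i).
4. **Dynamic threshold** th(i) = β·MA(i) + θ, where MA is a heartbeat-scale
   moving mean of l (half-window M = 150 at 360 Hz), β = 2.5, and θ is one
   quarter of the mean of l over the 300-sample initialisation buffer
   (or the fixed trained value 206 on MIT-BIH-scaled input).
5. **Candidate blocks**: maximal runs with l(i) > th(i).
6. **Peak search**: per block (tiled at 60 ms), the argmax of y; then a
   refractory correction removes the weaker of any two peaks closer than
   272 ms (98 samples at 360 Hz).

Because detection happens on |ŷ| and θ scales with the input power, the
detector is invariant to QRS polarity and (in auto-θ mode) to input gain.

Evaluation follows the AAMI beat-by-beat convention: one-to-one matching
within ±150 ms, then
S = TP/(TP+FN), P = TP/(TP+FP), DER = (FN+FP)/(TP+FN), in percent.

## Worked example

```python
import triqrs as tq

cfg = tq.derive_config(360)              # N=25, s=7, L=5, M=150
beat, noise = tq.preset("noisy_baseline")
signal, truth = tq.generate(60, 360, bpm=72, hrv_fraction=0.05,
                            beat=beat, noise=noise, seed=42)
peaks, trace = tq.detect(signal, cfg)
m = tq.match_beats(truth.indices, peaks.indices, tolerance_ms=50, fs=360)
print(tq.metrics_table({"synthetic": m}).to_string(index=False))
```

prints

```
   Record  Total  TP  FN  FP  S(%)  P(%)  DER(%)
synthetic     72  72   0   0 100.0 100.0     0.0
```

— 72 simulated beats at 72 bpm under strong baseline wander, all 72 found
within ±50 ms of ground truth with no false positives. The first detected
peak times (`peaks.times_s[:5]`) are `[0.417 1.272 2.103 2.964 3.811]`,
matching the jittered ≈0.83 s RR intervals the generator placed. The same
record processed sample-by-sample (`tq.detect_stream(signal.samples, cfg)`)
yields the identical peak list.

The same workflow is available from the shell:

```sh
triqrs simulate --duration-s 30 --bpm 72 --seed 5 --out sim.csv --truth truth.csv
triqrs detect --input sim.csv --fs 360 --out peaks.csv
triqrs evaluate --input record.hea --ann atr        # WFDB record + .atr
triqrs params --fs 360                              # derived parameter set
```

## Documentation

`docs/methods.md` describes the model, every tunable parameter with its
default and rationale, what the synthetic generator does and does not
emulate, the numerical design choices (boundary handling, recursive-filter
drift control, degenerate inputs), and known limitations.
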