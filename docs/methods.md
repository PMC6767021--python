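# Methods

## The detection model

The detector assumes a single-channel ECG in which the QRS complex is the
steepest, most compact deflection of each beat — not necessarily the
largest (tall P waves) nor of fixed polarity (negative QRS). Every stage is
chosen to be computable with O(1) arithmetic per sample:

1. **Moving-average high-pass.** ŷ(i) = x(i) − mean(x[i−N..i+N]);
   y = |ŷ|. Removes baseline wander (< ~0.5 Hz) and attenuates P/T waves,
   whose power concentrates below ~5 Hz; rectification makes the rest of
   the pipeline polarity-blind.
2. **Triangle template matching.** t(i) = max(0, (y(i)−y(i−s))(y(i)−y(i+s))).
   The product of the two slope differences is maximal at a triangular apex,
   negative (hence clamped to 0) on monotone segments, and small for
   broadband noise whose slopes decorrelate at lag s. Output units are
   squared amplitude.
3. **Moving-average low-pass.** l = mean(t[i−L..i+L]) suppresses the
   high-frequency components introduced by the nonlinear matching step.
4. **Dynamic threshold.** th(i) = β·MA(i) + θ with MA the centered mean of
   l over 2M+1 samples (~ one heartbeat). β controls candidate-block
   width; θ suppresses false positives between beats.
5. **Blocks and peak search.** Candidate blocks are maximal runs with
   l > th (strict). Each block is tiled into ≤ 60 ms windows and each tile
   contributes the argmax of y (ties to the earlier index); a refractory
   correction then removes the lower-amplitude member of any pair closer
   than 272 ms until the set is stable.

## Parameters

| Parameter | Meaning | Default (360 Hz) | Rationale |
|---|---|---|---|
| `fs_work` | working sampling rate | 360 Hz | common resampling target for the standard arrhythmia databases |
| `hp_cutoff` | high-pass cut-off | 5 Hz | P/T-wave and motion-artifact power lies below ~5 Hz |
| `N` | high-pass half-window | 25 | smallest N with fs/(2N+1) ≤ √2·5 Hz |
| `s` | template per-side span | 7 | ⌊0.020·fs⌋: 40 ms template, half the minimum normal QRS width |
| `lp_cutoff` | low-pass cut-off | 35 Hz | QRS energy in the matched output lies in ~5–35 Hz |
| `L` | low-pass half-window | 5 | smallest L with first boxcar null fs/(2L+1) ≤ 35 Hz |
| `M` | threshold-MA half-window | 150 | ≈ one heartbeat (301 samples ≈ 0.84 s); scales as round(150·fs/360) |
| `beta` | threshold multiplier | 2.5 | performance is flat for β in ~2–4; 2.5 keeps blocks narrow |
| `theta` | threshold offset | auto: mean(l over init buffer)/4 | power-scaled, making detection gain-invariant; fixed 206 provided for MIT-BIH-scaled ADC input |
| `refractory_ms` | min RR distance | 272 ms | ceiling heart rate ≈ 220 bpm; 98 samples at 360 Hz |
| `search_cap_ms` | per-tile search window | 60 ms | half of the 120 ms upper normal QRS width |
| `init_buffer_samples` | warm-up buffer | 300 | 0.833 s at 360 Hz; sets the θ estimate and the latency model |

**Window-selection rules.** The high-pass rule (smallest N with
fs/(2N+1) ≤ √2·fc) and the low-pass rule (smallest L with
fs/(2L+1) ≤ fc, the boxcar's first spectral null) are calibrations chosen
to reproduce the standard half-windows 25 and 5 at 360 Hz; the √2 factor
absorbs the gap between a boxcar's equivalent-width and −3 dB definitions
of "cut-off" (the moving-average subtractor's −3 dB point for N=25 sits
near 5.2 Hz, not exactly 5 Hz — no N makes it exact). The template rule
floors 0.020·fs; flooring vs rounding is unobservable at 360 Hz (both give
7) and flooring is fixed here.

**Refractory distance.** 272 ms corresponds to ≈ 220 bpm, slightly above
the ~206 bpm physiological ceiling usually quoted (60/206 ≈ 291 ms); the
shorter, more permissive distance is kept as the method's published
operating point.

## Numerical choices

- **Boundary policy.** Batch filters reflect-pad N (or L, M) samples at
  each end, so outputs keep the input length and no artificial edge
  transients appear; the template stage instead zeroes its first/last s
  samples (one slope segment would leave the signal). Streaming mode emits
  nothing for warm-up/lookahead samples and completes edges at
  end-of-stream with the identical padded computation.
- **Exact DC rejection.** Centered means are computed by
  shift-and-accumulate, mean(x)ᵢ = xᵢ − (2N+1)⁻¹Σⱼ(xᵢ − xᵢ₊ⱼ), so constant
  input gives exactly zero high-pass output and exactly-preserved low-pass
  output (every term cancels in floating point). Because each output
  sample's accumulation order is fixed, chunked recomputation is bitwise
  identical to whole-signal computation — the basis of the streaming ==
  batch guarantee.
- **Recursive drift control.** The O(1)-per-sample running-sum filters
  resynchronise their sum against a direct summation of the ring buffer
  every 8192 steps; observed disagreement with the direct form stays below
  1e-14 relative over 10⁶ samples, well inside the 1e-9 contract.
- **Threshold recursion.** The iterative threshold update is implemented
  as a recursive moving-average update followed by th = β·MA + θ; folding
  the constant θ into the per-sample recursion itself would accumulate it
  without bound.
- **Degenerate inputs.** Strict exceedance (l > th) plus a θ floor of
  16·ε times the initialisation buffer's peak means an all-zero or
  constant record yields no peaks; the floor scales with input power, so
  gain invariance is preserved. Inputs shorter than the largest window
  (2M+1 at default settings) are rejected with the limiting window named;
  streams shorter than that simply emit nothing.
- **Matching ties.** Beat-to-detection matching is greedy chronological
  with nearest-within-tolerance preference; equidistant ties take the
  earlier detection. The ±150 ms tolerance is the EC57 convention and is
  exposed as a flag.
- **Streaming emission.** A peak is emitted once its candidate cluster
  (chain of candidates separated by less than the refractory distance) is
  closed and the threshold frontier has passed beyond reach; clusters are
  resolved with the same globally-weakest-first elimination as batch mode,
  so the emitted sequence equals the batch peak list exactly. The current
  implementation retains the full sample history (memory grows linearly
  with stream length) while doing amortised O(1) work per sample;
  truncating retained history is a straightforward extension not needed
  for the target record lengths.

## The synthetic generator

Each beat is a sum of five Gaussians (P, Q, R, S, T) with amplitudes,
widths (σ, ms) and offsets from the R apex; defaults give a ≈100 ms QRS,
a 0.15 mV P wave and 0.3 mV T wave around a 1 mV R peak. Beats are placed
at RR = 60/bpm intervals, each perturbed by uniform ±hrv jitter, and every
R-apex sample index is returned as ground truth. Noise sources: sinusoidal
baseline wander (≤ 0.5 Hz), white Gaussian noise standing in for EMG
activity, and an optional powerline sinusoid. Presets: `clean`, `tall_p`
(P at 60% of R — the morphology that defeats amplitude-thresholding
detectors), `negative_qrs`, `noisy_baseline`, `emg_heavy`.

What this emulates: morphology, rate, jitter, polarity, gain, additive
stationary noise. What it does not: real arrhythmia sequences (flutter,
bigeminy), non-stationary noise bursts, electrode pop, paced beats, QRS
morphology change over time, or recording-specific ADC quantisation.
Perfect scores on the presets therefore demonstrate the detector's design
properties (slope selectivity, polarity/gain invariance, refractory
behaviour), not clinical-database performance; database benchmarks require
the real records and annotations.

## Known limitations

- M is fixed (normal-heart-rate prior); sustained tachycardia above the
  272 ms refractory ceiling or long flutter episodes will merge or drop
  beats. Adapting M to the running heart rate is the natural extension.
- The fixed θ = 206 is only meaningful on inputs scaled like the MIT-BIH
  ADC output; auto-θ is estimated once from the initialisation buffer and
  not re-estimated, so a large gain change mid-record can degrade
  sensitivity until amplitudes recross the threshold.
- The WFDB reader covers single-segment records in formats 212 and 16 with
  one `.dat` per record — the standard arrhythmia-database layout — and
  does not write annotation files.
- Evaluation matching is greedy; in pathological configurations (several
  detections crowded inside one tolerance window) a maximum-cardinality
  matcher could score one more TP. For refractory-constrained detections
  at physiologic rates the two agree.
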