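# Methods

This note documents the models, conventions and design choices behind
`beatguard`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic benchmarks do and do not show.

## Signal model and synthetic data

A beat is modeled as a baseline plus five Gaussian waves (P, Q, R, S, T),
each parameterized by amplitude (mV), center offset from the R-peak (s)
and width (s). This ECGSYN-style idealization is chosen because every
fiducial quantity then has a directly computable ground truth on the clean
waveform. A record is a train of such beats: beat times follow a mean
heart rate (default 72 bpm) with Gaussian RR jitter (default SD 30 ms, a
mid-range sinus variability); ventricular ectopics are drawn per beat with
a configurable probability, rendered from a wide-QRS/inverted-T template,
arrive early (prematurity factor 0.8) and are followed by a compensatory
pause (factor 1.5 on the next RR) — the classic RR_pre/RR_post asymmetry
of a PVC.

Three optional variability channels emulate real recordings: a per-beat
global gain (respiratory amplitude modulation), independent per-wave
gains, and a per-beat global width scale. They are off by default and
enabled in the benchmark presets.

Generator truth for onsets/offsets uses the same measurement convention
as the extractor (below) evaluated on the noise-free waveform. The
truth-recovery tests therefore check the pipeline (filtering,
segmentation, superposition of neighboring beats) rather than the
convention itself; that is the intended scope.

**What the generator does not model:** baseline wander and electrode
noise, morphology drift within a recording, fusion beats, atrial
fibrillation and other rhythm-level pathologies, multi-lead projection,
and sensor artifacts. Passing tests on this data demonstrate correctness
of the pipeline mechanics and internal consistency — not clinical
performance. Real-data benchmarks are delegated to the optional
`scripts/reproduce_mitbih.py`.

### Threat model

Five seeded attack types cover three families: signal manipulation
(additive Gaussian noise with SD = intensity × record SD; local time warp
by a factor 1 ± 0.3·intensity), false data injection / replay (overwrite
with a foreign synthetic rhythm; loop a captured ≤4 s clean window
verbatim across the span), and flatline/DoS (zeroed span). Intensity 0 is
the identity by contract. The intensity scale itself is a modeling choice
— published threat descriptions name attack classes, not magnitudes — and
is exposed in configuration. Replay is modeled as a short captured loop
because that is both the common attack pattern and the only variant a
bounded device-side history can in principle witness.

## Stage 1 — conditioning and segmentation

The conditioning filter is a 4th-order Butterworth bandpass, 0.5–40 Hz,
applied forward–backward. Zero-phase application preserves fiducial
timing; the effective magnitude response is the square of the 4th-order
design (verified in tests at 10 Hz and 60 Hz against the designed
response), and a `causal=True` option applies a literal single pass.
R-peak detection follows the canonical Pan–Tompkins recipe (5–15 Hz
detection bandpass, 5-point derivative, squaring, 150 ms moving-window
integration, adaptive dual thresholds with 1.66·RR search-back, 200 ms
refractory period), run on the conditioned signal, with detections
snapped to the local signal extremum within ±75 ms. Two robustness
additions: threshold initialization falls back to the global maximum when
the first 2 s are silent, and a global floor of 2% of the maximum
integrated energy keeps edge ripple on quiet records from being promoted
to beats. Beat windows are half-open `[R−100, R+156)` at 360 Hz; windows
crossing a record boundary are dropped and counted.

## Stage 2 — the 40-feature descriptor

Canonical order: statistical (6) → fiducial (13) → wavelet (12) → HRV (9).
Values that cannot be measured are masked, never zero-filled.

*Statistical.* Population moments; kurtosis is excess (normal → 0); an
exactly constant window (peak-to-peak 0) yields 0 for SD, skewness and
kurtosis by convention.

*Fiducial.* Search windows around the R-peak: Q = minimum in (R−80 ms,
R); S = minimum in (R, R+80 ms); T = largest baseline departure at a
genuine turning point in (R+100 ms, R+400 ms); P likewise in (R−250 ms,
min(R−60 ms, QRS onset − 10 ms)). The baseline is the median of the
flattest 40 ms chunk (20 ms stride) before R−60 ms. This estimator was
chosen over simpler rules (window head, fixed PR window) after both were
found to fail systematically: the window head tilts under zero-phase
filter recovery next to a wide ventricular beat, and a fixed PR window is
contaminated by wide-QRS onsets. Onsets/offsets are the nearest crossing
of baseline ± 5% of the R amplitude, with walks bounded to a local
neighborhood (60 ms for Q/S, 200 ms for T, 80 ms for P); a wave that
never returns to baseline inside its bound is reported absent rather than
guessed. Waves whose extremum does not clear 5% of |R| are absent; beats
with |R| < 0.05 mV are degenerate (everything absent). Ratios use
absolute magnitudes; a masked or zero denominator masks the ratio.

*Wavelet.* 4-level db4 decomposition in periodization mode, which keeps
the transform orthogonal so subband energies sum exactly to the signal
energy (Parseval is a tested invariant at 1e-6 relative). Per detail
level: energy, Shannon entropy of the normalized squared-coefficient
distribution (0·log 0 := 0; bounded by log₂ of the level's coefficient
count), and coefficient SD as the third metric. The third metric is a
deliberate completion — energy and entropy alone give 8 values where the
descriptor requires 12 — and can be switched to relative energy in
configuration.

*HRV / non-linear.* Computed on a trailing window of RR intervals
(default 32 beats, minimum 16 — shorter histories mask the whole group):
SDNN, RMSSD, pNN50 (>50 ms), mean RR, LF/HF (tachogram resampled at 4 Hz,
Welch periodogram, LF 0.04–0.15 Hz, HF 0.15–0.40 Hz), Poincaré SD1/SD2
from the lagged-pair variances (population convention; the identity
SD1² + SD2² = 2·SDNN_lag² is a tested invariant), their ratio, and sample
entropy with m = 2, r = 0.2·SD (both configurable). SampEn draws both
template lengths from the same n−m start positions; a constant series
gives 0 (all templates match), and series with no matches are masked.

## Stage 3 — model core

LightGBM is the classification engine; its internal second-order boosting
objective is used as-is. Defaults are the tuned operating point
(n_estimators 1450, max_depth 11, learning_rate 0.05, num_leaves 38,
subsample 0.85, colsample_bytree 0.75); tests and examples use smaller
deliberately-documented configurations (typically 50–300 trees) to keep
desk-scale runtimes in seconds. Training is seeded and bit-reproducible
(`deterministic`, single thread, fixed seed).

Class imbalance is handled by SMOTE, implemented from its definition:
each synthetic minority row is a convex combination of a minority point
and one of its k = 5 nearest minority neighbors; originals are preserved;
classes smaller than k+1 raise with a hint to lower k. Masked features
are imputed with training-set medians *before* SMOTE (interpolation needs
complete vectors); the medians travel with the model bundle so prediction
applies the same imputation. In cross-validation, imputation and SMOTE
happen inside training folds only.

The tuner maximizes stratified 5-fold cross-validated macro F1 over the
documented search space (n_estimators 500–2000, depth 5–15, learning rate
0.01–0.2, leaves 20–50, subsample/colsample 0.6–1.0). Two backends:
seeded uniform random sampling (default) and an exhaustive grid; the
backend is pluggable precisely so that no result depends on a specific
optimizer's trajectory.

Model bundles are JSON documents embedding the LightGBM text dump plus
feature names, classes, hyperparameters, seed and imputation medians —
diffable, versioned, and round-tripping bit-identically.

## Stage 4 — explanation

Attributions are exact path-dependent TreeSHAP values computed by the
tree ensemble itself; additivity (base value + contributions = margin of
the explained class) is enforced at 1e-6 and cross-checked in tests
against an exhaustive subset-enumeration Shapley oracle on small trees
(cover-weighted conditional expectations). For multiclass models the
explained class is the argmax; for binary models contributions are signed
toward the predicted class. Global importance is mean |SHAP| with ties
broken by canonical feature order, making rankings deterministic.

The prompt document is deterministic by construction: prediction summary
(label + confidence to the nearest percent), base value, top-K drivers
(K = 5 default, |SHAP|-ordered) each with measured value, SHAP value and
direction, plus a fixed instruction block mandating the four-section
output structure and evidence-only grounding. The shipped generator is a
fill-in template that mentions every driver and nothing outside the
prompt; an injected external generator that raises falls back to the
template with a warning.

## Security layer

Analysis windows are 2 s with 1 s hop. Each window yields ten integrity
features: normalized spectral entropy, sub-0.5 Hz and >40 Hz power
fractions, amplitude kurtosis, clipping fraction (|x| ≥ 3 mV — above any
physiologic amplitude), RR implausibility count (RR < 200 ms or
> 3000 ms), maximum correlation against a 5-window trailing buffer
(replay witness), exact-repeat flatline fraction, a device message-rate
proxy, and rhythm-tempo deviation (|window RR median − running RR median|
/ running median, with beats re-detected from the incoming signal, since
annotations on a tampered stream cannot be trusted). The tempo feature
exists because the first nine are structurally blind to temporal
distortion — the interior of a ±24% time warp is valid ECG at a shifted
rate — and a running-baseline rhythm consistency check is the minimal
monitor that exposes it.

The detector is a binary LightGBM over these features; the trust score is
T = 1 − p_attack, and an inference is flagged untrusted exactly when
T < τ (default 0.5; `tau_sweep` reports the metric battery across a τ
grid). Windows are labeled attacked when at least half their samples fall
under the attack mask. Trust flags annotate predictions; they never
suppress them — surfacing a low-trust warning alongside the clinical
output keeps the failure mode visible instead of silently dropping beats.

## Evaluation conventions

Per-class metrics come from explicit TP/TN/FP/FN counts; macro F1 is the
unweighted mean; multiclass AUC is macro one-vs-rest, masked for classes
absent from the truth. The ablation runner trains A1 (statistical, 6),
A2 (+fiducial, 19), A3 (+wavelet, 31), A4 (full, 40) with identical
hyperparameters and an identical stratified split; the cumulative counts
follow the four group sizes (6/13/12/9), which is why they read
6/19/31/40. Effect sizes report Δ = new − baseline and 100·Δ/baseline
(percent masked for zero baselines; displayed at 1–2 decimals, never
rounded internally). Exact binomial intervals are Clopper–Pearson via
Beta quantiles, with the k = 0 and k = n boundaries closed at 0 and 1.

## Benchmark constructions

`synth.two_class_benchmark` builds the N-vs-V dataset used by the
pipeline-level tests: the ventricular template is the normal template
with QRS widths and centers scaled 1.8× (R amplitude scaled by
1.8^−0.5 to preserve energy; Q/S deepened by 1.8^0.5, as ventricular
complexes are), T polarity inverted, plus the premature/pause rhythm
behavior — so the systematic class differences are QRS duration, T sign
and the pause. Per-beat gain (SD 0.2), per-wave gain (SD 0.08) and width
(SD 0.05) jitter ensure that raw amplitude statistics vary within each
class the way real recordings do; without that variability, any of a
dozen amplitude-derived features separates the classes perfectly and the
attribution ranking degenerates to an arbitrary tie-break. Under this
construction the model's top global attributions are QRS duration, T
amplitude and post-beat RR — the markers a cardiologist would check.

The IDS benchmark (`ids.build_attack_benchmark`) draws records at
60–90 bpm, attacks the middle third of each with every attack type at a
given intensity, and pools clean windows from unattacked copies. Problem
sizes throughout the suite (8–10 records of 60 s for training-scale sets,
2–4 for held-out sets, 50-beat fiducial sweeps, 100-fixture Parseval
checks) were chosen as the smallest sets at which the checked properties
are stable across seeds.

## Known limitations

- Fiducial detection assumes a dominant R-peak and monophasic waves; RSR′
  complexes are approximated, and QRS onset requires a detectable Q (a
  template without one, like the LBBB-style preset, reports the duration
  masked rather than substituting R onset).
- The LF/HF estimate on a 32-beat window is a coarse spectral summary;
  windows much shorter than a minute under-resolve the LF band.
- The IDS is trained and evaluated on the package's own threat simulator;
  transfer to real attack traffic is untested by design (see scope note
  above).
- Binary anomaly and 5-class models are trained separately; the binary
  AUC is the dedicated binary model's, not a collapse of the 5-class
  probabilities.
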