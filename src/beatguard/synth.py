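"""Ground-truthed synthetic ECG and the signal-level threat model.

Beat morphology is a sum of five Gaussian waves (P, Q, R, S, T) over a
baseline — the same idealization ECGSYN uses — so every fiducial quantity
(wave centers, amplitudes, Q-onset-to-S-offset span) has a closed-form or
directly computable ground truth.  Records are sequences of such beats with
sinus RR jitter; PVC-like beats are wide-QRS, inverted-T, premature beats
followed by a compensatory pause.

Attacks realize the three threat families an adversary on the wireless path
can mount: signal manipulation (noise injection, temporal distortion),
false-data injection / replay, and flatline/DoS-style disruption.  Every
attack is seeded and returns a per-sample mask of affected samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import (
    BEAT_LEN,
    POST_SAMPLES,
    PRE_SAMPLES,
    BeatAnnotation,
    BeatSegment,
    ECGRecord,
)

WAVE_NAMES = ("P", "Q", "R", "S", "T")

#: Fraction of the R amplitude used as the onset/offset crossing threshold.
ONSET_THRESHOLD_FRACTION = 0.05

ATTACK_TYPES = (
    "noise_injection",
    "temporal_distortion",
    "false_data_injection",
    "replay",
    "flatline_dos",
)

#: Attack families as grouped in the threat model.
ATTACK_FAMILIES = {
    "signal_manipulation": ("noise_injection", "temporal_distortion"),
    "injection_replay": ("false_data_injection", "replay"),
    "flatline_dos": ("flatline_dos",),
}


@dataclass(frozen=True)
class WaveParams:
    """Gaussian wave bank for one beat.

    ``waves`` maps each of P,Q,R,S,T to (amplitude mV, center offset from
    the R-peak in s, width SD in s).  An amplitude of exactly 0 marks the
    wave as absent.
    """

    waves: dict[str, tuple[float, float, float]]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        for name in WAVE_NAMES:
            if name not in self.waves:
                raise ValueError(f"missing wave {name}")
            amp, _center, width = self.waves[name]
            if width <= 0:
                raise ValueError(f"wave {name} width must be positive")
        if not self.waves["R"][0] > 0:
            raise ValueError("R amplitude must be positive for a valid beat")

    def amplitude(self, name: str) -> float:
        return self.waves[name][0]

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the beat waveform at times ``t`` (s, relative to R)."""
        x = np.full_like(np.asarray(t, dtype=float), self.baseline)
        for amp, center, width in self.waves.values():
            if amp != 0.0:
                x = x + amp * np.exp(-((t - center) ** 2) / (2.0 * width**2))
        return x


def _template(p, q, r, s, t, baseline=0.0) -> WaveParams:
    return WaveParams(dict(zip(WAVE_NAMES, (p, q, r, s, t))), baseline)


#: Textbook normal sinus beat (~86 ms QRS, upright T).
NORMAL_TEMPLATE = _template(
    p=(0.15, -0.18, 0.022),
    q=(-0.12, -0.030, 0.008),
    r=(1.10, 0.0, 0.012),
    s=(-0.25, 0.030, 0.009),
    t=(0.35, 0.28, 0.060),
)

#: PVC-like beat: absent P, wide QRS (Q-to-S trough span 124 ms), inverted T.
PVC_TEMPLATE = _template(
    p=(0.0, -0.18, 0.022),
    q=(-0.30, -0.062, 0.014),
    r=(1.30, 0.0, 0.028),
    s=(-0.40, 0.062, 0.015),
    t=(-0.45, 0.30, 0.070),
)

#: Distinct desk-scale morphologies for the five modeled beat classes.
CLASS_TEMPLATES: dict[str, WaveParams] = {
    "N": NORMAL_TEMPLATE,
    "L": _template(  # LBBB-like: broad R, discordant T, shallow wide Q
        p=(0.12, -0.19, 0.022),
        q=(-0.07, -0.050, 0.012),
        r=(1.00, 0.0, 0.026),
        s=(-0.30, 0.058, 0.018),
        t=(-0.30, 0.30, 0.065),
    ),
    "R": _template(  # RBBB-like: deep slurred S, modest R, flattened T
        p=(0.14, -0.18, 0.022),
        q=(-0.08, -0.032, 0.008),
        r=(0.80, 0.0, 0.013),
        s=(-0.65, 0.048, 0.018),
        t=(0.15, 0.29, 0.060),
    ),
    "V": PVC_TEMPLATE,
    "A": _template(  # APC-like: accentuated early P, otherwise narrow beat
        p=(0.28, -0.14, 0.016),
        q=(-0.10, -0.030, 0.008),
        r=(1.05, 0.0, 0.012),
        s=(-0.22, 0.030, 0.009),
        t=(0.30, 0.27, 0.055),
    ),
}


@dataclass(frozen=True)
class FiducialTruth:
    """Exact generator-side fiducials for one synthetic beat.

    Onsets/offsets are measured on the clean waveform with the same
    convention the feature extractor uses: the nearest crossing of
    baseline ± 5% of the R amplitude, walking outward from the trough.
    Times are in seconds relative to the R center; a ``None`` entry means
    the wave is absent from the template.
    """

    params: WaveParams
    r_amplitude: float
    q_trough: float | None
    s_trough: float | None
    q_onset: float | None
    s_offset: float | None
    t_peak: float | None
    t_amplitude: float | None
    p_peak: float | None
    p_amplitude: float | None

    @property
    def qrs_duration_ms(self) -> float | None:
        if self.q_onset is None or self.s_offset is None:
            return None
        return 1000.0 * (self.s_offset - self.q_onset)


def _walk_to_crossing(x: np.ndarray, start: int, step: int,
                      baseline: float, thresh: float,
                      max_steps: int | None = None) -> int | None:
    i = start
    steps = 0
    while 0 <= i < x.size and (max_steps is None or steps <= max_steps):
        if abs(x[i] - baseline) < thresh:
            return i
        i += step
        steps += 1
    return None


def synth_beat(params: WaveParams, fs: float = 360.0,
               n_samples: int = BEAT_LEN) -> tuple[BeatSegment, FiducialTruth]:
    """Render one beat on a window anchored at the R center.

    The R center sits at sample ``round(n_samples * 100 / 256)`` so the
    default geometry matches the pipeline's segmentation window.
    """
    if n_samples < 64:
        raise ValueError("n_samples must be at least 64")
    if fs <= 0:
        raise ValueError("fs must be positive")
    r_idx = int(round(n_samples * PRE_SAMPLES / BEAT_LEN))
    t = (np.arange(n_samples) - r_idx) / fs
    x = params.evaluate(t)
    seg = BeatSegment(x, fs, r_index=r_idx)

    # reference level and threshold mirror the measurement convention:
    # flattest pre-QRS chunk as baseline, 5%-of-R crossing
    from .features import isoelectric_level

    b = isoelectric_level(x, r_idx, fs)
    r_amp = float(x[r_idx] - b)
    thresh = ONSET_THRESHOLD_FRACTION * abs(r_amp)

    def trough(lo_s: float, hi_s: float) -> int:
        lo = max(0, r_idx + int(round(lo_s * fs)))
        hi = min(n_samples, r_idx + int(round(hi_s * fs)))
        return lo + int(np.argmin(x[lo:hi]))

    q_i = trough(-0.080, 0.0) if params.amplitude("Q") != 0 else None
    s_i = trough(0.0, 0.080) if params.amplitude("S") != 0 else None
    # a wave that does not clear the crossing threshold on the rendered
    # waveform is absent by the measurement convention
    if q_i is not None and abs(x[q_i] - b) < thresh:
        q_i = None
    if s_i is not None and abs(x[s_i] - b) < thresh:
        s_i = None
    bound = int(round(0.060 * fs))
    q_on = s_off = None
    if q_i is not None:
        w = _walk_to_crossing(x, q_i, -1, b, thresh, bound)
        q_on = None if w is None else (w - r_idx) / fs
    if s_i is not None:
        w = _walk_to_crossing(x, s_i, +1, b, thresh, bound)
        s_off = None if w is None else (w - r_idx) / fs

    t_peak = t_amp = None
    if params.amplitude("T") != 0:
        lo = r_idx + int(round(0.100 * fs))
        hi = min(n_samples, r_idx + int(round(0.400 * fs)))
        k = lo + int(np.argmax(np.abs(x[lo:hi] - b)))
        t_peak, t_amp = (k - r_idx) / fs, x[k] - b
    p_peak = p_amp = None
    if params.amplitude("P") != 0:
        lo = max(0, r_idx + int(round(-0.250 * fs)))
        hi = r_idx + int(round(-0.060 * fs))
        k = lo + int(np.argmax(np.abs(x[lo:hi] - b)))
        p_peak, p_amp = (k - r_idx) / fs, x[k] - b

    truth = FiducialTruth(
        params=params,
        r_amplitude=x[r_idx] - b,
        q_trough=None if q_i is None else (q_i - r_idx) / fs,
        s_trough=None if s_i is None else (s_i - r_idx) / fs,
        q_onset=q_on,
        s_offset=s_off,
        t_peak=t_peak,
        t_amplitude=t_amp,
        p_peak=p_peak,
        p_amplitude=p_amp,
    )
    return seg, truth


def scale_amplitudes(params: WaveParams, gain: float) -> WaveParams:
    """Multiply every wave amplitude by ``gain`` (respiratory-style gain)."""
    waves = {n: (a * gain, c, w) for n, (a, c, w) in params.waves.items()}
    return WaveParams(waves, params.baseline)


def widen_qrs(params: WaveParams, width_scale: float,
              invert_t: bool = True,
              preserve_energy: bool = True) -> WaveParams:
    """A variant differing from ``params`` only in QRS width (+ T sign).

    Q/R/S widths and center offsets scale by ``width_scale``; with
    ``preserve_energy`` their amplitudes scale by ``width_scale**-0.5`` so
    the beat's energy stays comparable and the duration itself carries the
    class signal.  Useful for constructing ventricular-style beats whose
    only systematic differences are QRS duration, T polarity and the
    compensatory pause.
    """
    waves = dict(params.waves)
    for name in ("Q", "R", "S"):
        a, c, w = waves[name]
        if name == "R":
            # the dominant R trades amplitude for width, keeping energy
            scale = width_scale ** -0.5 if preserve_energy else 1.0
        else:
            # Q/S deepen with width, as ventricular complexes do; this
            # also keeps them detectable above the amplitude floor when
            # their own tails depress the PR-segment baseline estimate
            scale = width_scale ** 0.5
        waves[name] = (a * scale, c * width_scale, w * width_scale)
    if invert_t:
        a, c, w = waves["T"]
        waves["T"] = (-a, c, w)
    return WaveParams(waves, params.baseline)


@dataclass(frozen=True)
class RhythmSpec:
    """Rhythm-level recipe for a synthetic record."""

    mean_hr_bpm: float = 72.0
    rr_jitter_sd: float = 0.03
    pvc_probability: float = 0.0
    pvc_template: WaveParams = PVC_TEMPLATE
    normal_template: WaveParams = NORMAL_TEMPLATE
    compensatory_pause: float = 1.5
    premature_factor: float = 0.8
    amplitude_jitter: float = 0.0   # SD of per-beat global gain
    wave_jitter: float = 0.0        # SD of per-beat per-wave gain
    width_jitter: float = 0.0       # SD of per-beat global width gain
    duration: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvc_probability <= 1.0:
            raise ValueError("PVC probability must lie in [0, 1]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.mean_hr_bpm <= 0:
            raise ValueError("mean heart rate must be positive")


@dataclass
class RecordTruth:
    """Per-beat generator truth accompanying a synthetic record."""

    r_times: np.ndarray
    labels: list[str]
    beat_truths: list[FiducialTruth]


def synth_record(spec: RhythmSpec, fs: float = 360.0
                 ) -> tuple[ECGRecord, RecordTruth]:
    """Generate a record with ground-truth annotations; seeded, deterministic."""
    rng = np.random.default_rng(spec.seed)
    rr_base = 60.0 / spec.mean_hr_bpm
    t0 = PRE_SAMPLES / fs + 0.025
    t_max = spec.duration - POST_SAMPLES / fs

    times: list[float] = []
    labels: list[str] = []
    t = t0
    while t <= t_max:
        is_pvc = bool(rng.random() < spec.pvc_probability)
        times.append(t)
        labels.append("V" if is_pvc else "N")
        rr = rr_base + rng.normal(0.0, spec.rr_jitter_sd) \
            if spec.rr_jitter_sd > 0 else rr_base
        rr = max(rr, 0.3)
        if is_pvc:
            rr *= spec.compensatory_pause  # pause after the PVC
        t = t + rr

    # PVC prematurity: the ectopic beat arrives early within its interval
    times_arr = np.array(times)
    for i, lab in enumerate(labels):
        if lab == "V" and i > 0:
            gap = times_arr[i] - times_arr[i - 1]
            times_arr[i] = times_arr[i - 1] + gap * spec.premature_factor

    n = int(round(spec.duration * fs))
    x = np.zeros(n)
    tgrid = np.arange(n) / fs
    beat_truths: list[FiducialTruth] = []
    for bt, lab in zip(times_arr, labels):
        tpl = spec.pvc_template if lab == "V" else spec.normal_template
        if spec.amplitude_jitter > 0:
            gain = max(0.5, 1.0 + rng.normal(0.0, spec.amplitude_jitter))
            tpl = scale_amplitudes(tpl, gain)
        if spec.wave_jitter > 0 or spec.width_jitter > 0:
            wscale = max(0.6, 1.0 + rng.normal(0.0, spec.width_jitter)) \
                if spec.width_jitter > 0 else 1.0
            waves = {}
            for name, (a, c, w) in tpl.waves.items():
                g = max(0.3, 1.0 + rng.normal(0.0, spec.wave_jitter)) \
                    if spec.wave_jitter > 0 else 1.0
                waves[name] = (a * g, c * wscale, w * wscale)
            tpl = WaveParams(waves, tpl.baseline)
        lo = max(0, int((bt - 0.6) * fs))
        hi = min(n, int((bt + 0.7) * fs))
        x[lo:hi] += tpl.evaluate(tgrid[lo:hi] - bt) - tpl.baseline
        _, truth = synth_beat(tpl, fs)
        beat_truths.append(truth)
    x += spec.normal_template.baseline

    annotations = [
        BeatAnnotation(int(round(bt * fs)), lab)
        for bt, lab in zip(times_arr, labels)
    ]
    rec = ECGRecord(
        record_id=f"synth-{spec.seed}", fs=fs, samples=x,
        lead="MLII", annotations=annotations,
    )
    return rec, RecordTruth(times_arr, labels, beat_truths)


def two_class_benchmark(n_records: int = 10, seed: int = 0,
                        duration: float = 60.0,
                        pvc_probability: float = 0.3,
                        width_scale: float = 1.8
                        ) -> list[ECGRecord]:
    """Desk-scale N-vs-V benchmark records.

    The ventricular class differs from the normal class only in QRS width
    (scaled 1.8×, energy-preserving), T polarity and the compensatory
    pause; per-beat gain (SD 0.2), per-wave gain (SD 0.08) and width
    (SD 0.05) variability emulate the respiratory and morphological
    drift of real recordings so amplitude statistics do not separate the
    classes on their own.
    """
    v_template = widen_qrs(NORMAL_TEMPLATE, width_scale)
    records = []
    for i in range(n_records):
        spec = RhythmSpec(
            duration=duration,
            pvc_probability=pvc_probability,
            pvc_template=v_template,
            amplitude_jitter=0.2,
            wave_jitter=0.08,
            width_jitter=0.05,
            seed=seed + i,
        )
        records.append(synth_record(spec)[0])
    return records


@dataclass(frozen=True)
class AttackScenario:
    """A typed, seeded corruption applied to a span of a record."""

    type: str
    intensity: float
    start: float
    end: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.type not in ATTACK_TYPES:
            raise ValueError(
                f"unknown attack type {self.type!r}; expected one of "
                f"{ATTACK_TYPES}"
            )
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity must lie in [0, 1]")
        if self.end <= self.start or self.start < 0:
            raise ValueError("attack span must satisfy 0 <= start < end")


def inject_attack(record: ECGRecord, scenario: AttackScenario
                  ) -> tuple[ECGRecord, np.ndarray]:
    """Apply ``scenario`` and return (attacked record, per-sample mask)."""
    fs = record.fs
    n = record.samples.size
    i0 = int(round(scenario.start * fs))
    i1 = int(round(scenario.end * fs))
    if i1 > n:
        raise ValueError("attack span extends beyond the record")
    x = record.samples.copy()
    mask = np.zeros(n, dtype=bool)
    out = ECGRecord(record.record_id, fs, x, lead=record.lead,
                    annotations=list(record.annotations))
    if scenario.intensity == 0.0:
        return out, mask

    rng = np.random.default_rng(scenario.seed)
    span = slice(i0, i1)
    m = i1 - i0
    if scenario.type == "noise_injection":
        sd = scenario.intensity * float(np.std(record.samples))
        x[span] += rng.normal(0.0, sd, m)
    elif scenario.type == "temporal_distortion":
        sign = 1.0 if rng.random() < 0.5 else -1.0
        factor = 1.0 + sign * 0.3 * scenario.intensity
        src = i0 + np.arange(m) / factor
        src = np.clip(src, 0, n - 1)
        x[span] = np.interp(src, np.arange(n), record.samples)
    elif scenario.type == "false_data_injection":
        foreign_spec = RhythmSpec(
            mean_hr_bpm=110.0, rr_jitter_sd=0.01,
            normal_template=PVC_TEMPLATE,
            duration=max(m / fs + 2.0, 3.0),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        foreign, _ = synth_record(foreign_spec, fs)
        x[span] = foreign.samples[:m]
    elif scenario.type == "replay":
        # the attacker captures the clean window just before the span
        # (at most 4 s) and loops it verbatim across the span
        cap = min(m, int(round(4.0 * fs)))
        src0 = max(0, i0 - cap)
        window = record.samples[src0:src0 + cap]
        reps = int(np.ceil(m / cap))
        x[span] = np.tile(window, reps)[:m]
    elif scenario.type == "flatline_dos":
        x[span] = 0.0
    mask[span] = True
    out.samples = x
    return out, mask
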