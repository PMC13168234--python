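"""The 40-feature hybrid beat descriptor.

Four groups, concatenated in canonical order:

* statistical (6): mean, SD, peak-to-peak, skewness, excess kurtosis, RMS —
  population-moment conventions, degenerate (constant) beats yield 0 for
  skewness/kurtosis;
* fiducial (13): RR pre/post, QRS duration, QT interval, P duration (ms)
  and P/Q/R/S/T amplitudes (mV, baseline-corrected, signed) plus |R/S|,
  |P/R|, |T/R| ratios;
* wavelet (12): 4-level db4 DWT; per detail level cD1..cD4 the energy,
  Shannon entropy of the normalized squared-coefficient distribution
  (0·log 0 := 0), and coefficient SD;
* HRV / non-linear (9): SDNN, RMSSD, pNN50, mean RR, LF/HF ratio, Poincaré
  SD1, SD2, SD1/SD2 and sample entropy over a trailing RR window.

Quantities that cannot be measured (absent waves, short RR history) are
masked, never silently zeroed or fabricated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .records import BEAT_LEN, BeatSegment, RRContext

STATISTICAL_NAMES = ("mean", "std", "ptp", "skewness", "kurtosis", "rms")
FIDUCIAL_NAMES = (
    "rr_pre", "rr_post", "qrs_duration", "qt_interval", "p_duration",
    "p_amplitude", "q_amplitude", "r_amplitude", "s_amplitude", "t_amplitude",
    "rs_ratio", "pr_ratio", "tr_ratio",
)
WAVELET_NAMES = tuple(
    f"dwt_{metric}_d{level}"
    for level in (1, 2, 3, 4)
    for metric in ("energy", "entropy", "std")
)
HRV_NAMES = (
    "sdnn", "rmssd", "pnn50", "mean_rr", "lf_hf_ratio",
    "sd1", "sd2", "sd1_sd2_ratio", "sampen",
)

FEATURE_NAMES: tuple[str, ...] = (
    STATISTICAL_NAMES + FIDUCIAL_NAMES + WAVELET_NAMES + HRV_NAMES
)
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "statistical": STATISTICAL_NAMES,
    "fiducial": FIDUCIAL_NAMES,
    "wavelet": WAVELET_NAMES,
    "hrv_nonlinear": HRV_NAMES,
}
N_FEATURES = len(FEATURE_NAMES)  # 40

#: Wave-presence and onset/offset threshold, as a fraction of |R| amplitude.
AMPLITUDE_FLOOR_FRACTION = 0.05
#: Minimum |R| amplitude (mV) for a beat to count as having an R wave at all.
MIN_R_AMPLITUDE = 0.05
#: Default minimum RR-history length for the HRV group.
MIN_RR_HISTORY = 16


@dataclass
class FiducialPoints:
    """Window-relative fiducial times (s) and baseline-corrected amplitudes.

    ``None`` marks an absent wave (no extremum clears the amplitude floor).
    """

    baseline: float
    r_time: float | None = None
    r_amplitude: float | None = None
    q_trough: float | None = None
    q_amplitude: float | None = None
    q_onset: float | None = None
    s_trough: float | None = None
    s_amplitude: float | None = None
    s_offset: float | None = None
    t_peak: float | None = None
    t_amplitude: float | None = None
    t_offset: float | None = None
    p_peak: float | None = None
    p_amplitude: float | None = None
    p_onset: float | None = None
    p_offset: float | None = None


@dataclass
class FeatureVector:
    """The named 40-dimensional descriptor with a missing-value mask."""

    values: np.ndarray
    mask: np.ndarray  # True where the value is missing/masked
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.size != len(self.names) or self.mask.size != self.values.size:
            raise ValueError("feature vector must carry exactly "
                             f"{len(self.names)} named entries")
        if np.any(~np.isfinite(self.values[~self.mask])):
            raise ValueError("unmasked feature values must be finite")

    def as_dict(self) -> dict[str, float | None]:
        return {
            n: (None if m else float(v))
            for n, v, m in zip(self.names, self.values, self.mask)
        }


# ---------------------------------------------------------------------------
# (A) statistical
# ---------------------------------------------------------------------------

def statistical_features(beat: BeatSegment) -> np.ndarray:
    """Mean, SD, PTP, skewness, excess kurtosis, RMS (population moments)."""
    x = beat.samples
    mu = float(np.mean(x))
    ptp = float(np.max(x) - np.min(x))
    if ptp == 0.0:  # exactly constant: degenerate moments by convention
        sd = skew = kurt = 0.0
    elif (sd := float(np.sqrt(np.mean((x - mu) ** 2)))) == 0.0:
        skew = kurt = 0.0
    else:
        z = (x - mu) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
    rms = float(np.sqrt(np.mean(x**2)))
    return np.array([mu, sd, ptp, skew, kurt, rms])


# ---------------------------------------------------------------------------
# (B) fiducial
# ---------------------------------------------------------------------------

def _search_extremum(x: np.ndarray, lo: int, hi: int, mode: str,
                     baseline: float) -> tuple[int, float] | None:
    lo, hi = max(0, lo), min(x.size, hi)
    if hi <= lo:
        return None
    seg = x[lo:hi]
    if mode == "min":
        k = int(np.argmin(seg))
    else:
        # signed extremum: the genuine local turning point (slope sign
        # change) with the largest departure from baseline; a monotone
        # flank of a neighboring wave (e.g. a wide QRS edge inside the P
        # window) has no turning point and yields no wave
        d = np.diff(seg)
        turning = np.where(d[:-1] * d[1:] <= 0)[0] + 1
        turning = turning[(turning > 0) & (turning < len(seg) - 1)]
        if turning.size == 0:
            return None
        k = int(turning[np.argmax(np.abs(seg[turning] - baseline))])
    return lo + k, float(x[lo + k])


def _crossing(x: np.ndarray, start: int, step: int, baseline: float,
              thresh: float, max_steps: int | None = None) -> int | None:
    """Walk from ``start`` until |x - baseline| drops below ``thresh``.

    The walk is bounded to a local neighborhood (``max_steps``); an
    onset/offset that never returns to baseline inside it cannot be
    measured and is reported absent (None) rather than guessed.
    """
    i = start
    steps = 0
    while 0 <= i < x.size and (max_steps is None or steps <= max_steps):
        if abs(x[i] - baseline) < thresh:
            return i
        i += step
        steps += 1
    return None


def isoelectric_level(x: np.ndarray, r: int, fs: float) -> float:
    """Robust isoelectric baseline: median of the flattest 40 ms chunk
    before R−60 ms (20 ms stride).

    A fixed PR window can be contaminated by a wide QRS onset, and the
    window head can be tilted by filter recovery after a neighboring wide
    beat; picking the flattest pre-QRS chunk sidesteps both.
    """
    hi = r - int(round(0.060 * fs))
    w = max(2, int(round(0.040 * fs)))
    step = max(1, int(round(0.020 * fs)))
    best, best_var = None, np.inf
    for lo in range(0, max(1, hi - w + 1), step):
        chunk = x[lo:lo + w]
        v = float(np.var(chunk))
        if v < best_var:
            best, best_var = chunk, v
    if best is None:
        best = x[:max(2, min(20, x.size))]
    return float(np.median(best))


def locate_fiducials(beat: BeatSegment, fs: float | None = None
                     ) -> FiducialPoints:
    """Find P/Q/R/S/T landmarks with fixed search windows around the R-peak.

    Search windows: Q = minimum in (R−80 ms, R); S = minimum in
    (R, R+80 ms); T = signed extremum in (R+100 ms, R+400 ms); P = signed
    extremum in (R−250 ms, min(R−60 ms, QRS onset)).  Onsets/offsets are
    the nearest crossings of baseline ± 5% of |R|, with the baseline taken
    from the flattest pre-QRS chunk (``isoelectric_level``).  Degraded
    beats come back flagged, not thrown.
    """
    fs = beat.fs if fs is None else fs
    x = beat.samples
    r = beat.r_index
    baseline = isoelectric_level(x, r, fs)
    fid = FiducialPoints(baseline=baseline)

    r_amp = float(x[r] - baseline)
    if abs(r_amp) < MIN_R_AMPLITUDE:
        return fid  # flat/degenerate window: everything absent
    fid.r_time = r / fs
    fid.r_amplitude = r_amp
    floor = AMPLITUDE_FLOOR_FRACTION * abs(r_amp)

    def ms(v: float) -> int:
        return int(round(v * fs))

    q = _search_extremum(x, r - ms(0.080), r, "min", baseline)
    if q is not None and abs(q[1] - baseline) >= floor:
        fid.q_trough = q[0] / fs
        fid.q_amplitude = q[1] - baseline
        on = _crossing(x, q[0], -1, baseline, floor, ms(0.060))
        fid.q_onset = None if on is None else on / fs

    s = _search_extremum(x, r + 1, r + ms(0.080), "min", baseline)
    if s is not None and abs(s[1] - baseline) >= floor:
        fid.s_trough = s[0] / fs
        fid.s_amplitude = s[1] - baseline
        off = _crossing(x, s[0], +1, baseline, floor, ms(0.060))
        fid.s_offset = None if off is None else off / fs

    t = _search_extremum(x, r + ms(0.100), r + ms(0.400), "extremum", baseline)
    if t is not None and abs(t[1] - baseline) >= floor:
        fid.t_peak = t[0] / fs
        fid.t_amplitude = t[1] - baseline
        off = _crossing(x, t[0], +1, baseline, floor, ms(0.200))
        fid.t_offset = None if off is None else off / fs

    # the P search must end before the QRS begins: wide complexes push
    # their onset past R-60 ms and would otherwise masquerade as a P wave
    p_hi = r - ms(0.060)
    if fid.q_onset is not None:
        p_hi = min(p_hi, int(round(fid.q_onset * fs)) - ms(0.010))
    p = _search_extremum(x, r - ms(0.250), p_hi, "extremum", baseline)
    if p is not None and abs(p[1] - baseline) >= floor:
        fid.p_peak = p[0] / fs
        fid.p_amplitude = p[1] - baseline
        on = _crossing(x, p[0], -1, baseline, floor, ms(0.080))
        off = _crossing(x, p[0], +1, baseline, floor, ms(0.080))
        fid.p_onset = None if on is None else on / fs
        fid.p_offset = None if off is None else off / fs
    return fid


def _ratio(num: float | None, den: float | None) -> float | None:
    if num is None or den is None or den == 0.0:
        return None
    return abs(num) / abs(den)


def fiducial_features(fid: FiducialPoints, rr: RRContext
                      ) -> tuple[np.ndarray, np.ndarray]:
    """The 13 interval/morphology values (ms / mV); absent waves masked."""
    def span_ms(a: float | None, b: float | None) -> float | None:
        if a is None or b is None:
            return None
        return 1000.0 * (b - a)

    vals: list[float | None] = [
        rr.rr_pre,
        rr.rr_post,
        span_ms(fid.q_onset, fid.s_offset),          # qrs_duration
        span_ms(fid.q_onset, fid.t_offset),          # qt_interval
        span_ms(fid.p_onset, fid.p_offset),          # p_duration
        fid.p_amplitude,
        fid.q_amplitude,
        fid.r_amplitude,
        fid.s_amplitude,
        fid.t_amplitude,
        _ratio(fid.r_amplitude, fid.s_amplitude),    # |R/S|
        _ratio(fid.p_amplitude, fid.r_amplitude),    # |P/R|
        _ratio(fid.t_amplitude, fid.r_amplitude),    # |T/R|
    ]
    mask = np.array([v is None for v in vals])
    out = np.array([0.0 if v is None else float(v) for v in vals])
    return out, mask


# ---------------------------------------------------------------------------
# (C) wavelet
# ---------------------------------------------------------------------------

@dataclass
class WaveletDecomposition:
    """4-level db4 decomposition with per-level energy and entropy."""

    cA4: np.ndarray
    details: list[np.ndarray]  # cD1..cD4 in that order
    wavelet: str = "db4"
    energies: np.ndarray = field(default=None)  # type: ignore[assignment]
    entropies: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.energies = np.array([float(np.sum(d**2)) for d in self.details])
        self.entropies = np.array(
            [_shannon_entropy(d) for d in self.details]
        )


def _shannon_entropy(coeffs: np.ndarray) -> float:
    energy = float(np.sum(coeffs**2))
    if energy == 0.0:
        return 0.0
    p = coeffs**2 / energy
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def dwt_decompose(beat: BeatSegment, wavelet: str = "db4",
                  levels: int = 4) -> WaveletDecomposition:
    if beat.samples.size != BEAT_LEN:
        raise ValueError(f"wavelet features require {BEAT_LEN}-sample beats")
    # periodization keeps the transform orthogonal, so subband energies
    # sum exactly to the signal energy (Parseval)
    coeffs = pywt.wavedec(beat.samples, wavelet, level=levels,
                          mode="periodization")
    cA4, rest = coeffs[0], coeffs[1:]  # rest = [cD4, cD3, cD2, cD1]
    details = list(rest[::-1])
    return WaveletDecomposition(cA4=cA4, details=details, wavelet=wavelet)


def wavelet_features(beat: BeatSegment, third_metric: str = "std"
                     ) -> np.ndarray:
    """Energy, entropy and coefficient SD (or relative energy) per cD level."""
    dec = dwt_decompose(beat)
    total = float(np.sum(dec.cA4**2) + np.sum(dec.energies))
    out: list[float] = []
    for level, d in enumerate(dec.details):
        energy = dec.energies[level]
        entropy = dec.entropies[level]
        if third_metric == "std":
            third = float(np.std(d))
        elif third_metric == "relative_energy":
            third = float(energy / total) if total > 0 else 0.0
        else:
            raise ValueError(f"unknown third wavelet metric {third_metric!r}")
        out.extend([energy, entropy, third])
    return np.array(out)


# ---------------------------------------------------------------------------
# (D) HRV / non-linear
# ---------------------------------------------------------------------------

def sample_entropy(series: np.ndarray, m: int = 2,
                   r: float | None = None) -> float | None:
    """SampEn(m, r) = −ln(A/B) with self-matches excluded.

    ``r`` defaults to 0.2·SD of the series.  Returns 0.0 for a constant
    series (every template matches); ``None`` when no templates match.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < m + 2:
        return None
    sd = float(np.std(x))
    if r is None:
        r = 0.2 * sd
    if sd == 0.0:
        return 0.0

    # both template lengths draw from the same n-m start positions so
    # every m-template has an (m+1)-extension (standard definition)
    def count(mm: int) -> int:
        limit = n - m
        total = 0
        for i in range(limit):
            for j in range(i + 1, limit):
                if np.max(np.abs(x[i:i + mm] - x[j:j + mm])) <= r:
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if b == 0 or a == 0:
        return None
    return float(-math.log(a / b))


def poincare_descriptors(rr_ms: np.ndarray) -> tuple[float, float]:
    """SD1/SD2 from lagged RR pairs, population-variance convention."""
    rr = np.asarray(rr_ms, dtype=float)
    d = rr[1:] - rr[:-1]
    s = rr[1:] + rr[:-1]
    sd1 = float(np.sqrt(0.5 * np.var(d)))
    sd2 = float(np.sqrt(0.5 * np.var(s)))
    return sd1, sd2


def lf_hf_ratio(rr_ms: np.ndarray, resample_hz: float = 4.0) -> float | None:
    """LF(0.04–0.15 Hz)/HF(0.15–0.4 Hz) power ratio of the RR tachogram."""
    rr = np.asarray(rr_ms, dtype=float) / 1000.0
    if rr.size < 4:
        return None
    t = np.cumsum(rr)
    t = t - t[0]
    if t[-1] <= 0:
        return None
    grid = np.arange(0.0, t[-1], 1.0 / resample_hz)
    if grid.size < 8:
        return None
    tach = np.interp(grid, t, rr)
    tach = tach - np.mean(tach)
    nperseg = min(256, grid.size)
    f, pxx = sps.welch(tach, fs=resample_hz, nperseg=nperseg)
    lf = float(np.trapezoid(pxx[(f >= 0.04) & (f < 0.15)],
                            f[(f >= 0.04) & (f < 0.15)]))
    hf = float(np.trapezoid(pxx[(f >= 0.15) & (f < 0.40)],
                            f[(f >= 0.15) & (f < 0.40)]))
    if hf == 0.0:
        return None
    return lf / hf


def hrv_nonlinear_features(rr: RRContext, min_history: int = MIN_RR_HISTORY,
                           sampen_m: int = 2, sampen_r_factor: float = 0.2
                           ) -> tuple[np.ndarray, np.ndarray]:
    """SDNN, RMSSD, pNN50, mean RR, LF/HF, SD1, SD2, SD1/SD2, SampEn."""
    hist = rr.rr_history
    if hist.size < min_history:
        return np.zeros(len(HRV_NAMES)), np.ones(len(HRV_NAMES), dtype=bool)
    d = np.diff(hist)
    sdnn = float(np.std(hist))
    rmssd = float(np.sqrt(np.mean(d**2))) if d.size else 0.0
    pnn50 = float(np.mean(np.abs(d) > 50.0)) if d.size else 0.0
    mean_rr = float(np.mean(hist))
    lfhf = lf_hf_ratio(hist)
    sd1, sd2 = poincare_descriptors(hist)
    ratio = sd1 / sd2 if sd2 > 0 else None
    sd = float(np.std(hist))
    sampen = sample_entropy(hist, m=sampen_m, r=sampen_r_factor * sd)
    vals = [sdnn, rmssd, pnn50, mean_rr, lfhf, sd1, sd2, ratio, sampen]
    mask = np.array([v is None for v in vals])
    out = np.array([0.0 if v is None else float(v) for v in vals])
    return out, mask


# ---------------------------------------------------------------------------
# full descriptor
# ---------------------------------------------------------------------------

def extract_features(beat: BeatSegment, rr: RRContext,
                     fs: float | None = None,
                     third_wavelet_metric: str = "std",
                     min_rr_history: int = MIN_RR_HISTORY) -> FeatureVector:
    """Concatenate the four groups into the canonical 40-entry descriptor."""
    fs = beat.fs if fs is None else fs
    stat = statistical_features(beat)
    fid = locate_fiducials(beat, fs)
    fid_vals, fid_mask = fiducial_features(fid, rr)
    wav = wavelet_features(beat, third_metric=third_wavelet_metric)
    hrv_vals, hrv_mask = hrv_nonlinear_features(rr, min_history=min_rr_history)

    values = np.concatenate([stat, fid_vals, wav, hrv_vals])
    mask = np.concatenate([
        np.zeros(stat.size, dtype=bool),
        fid_mask,
        np.zeros(wav.size, dtype=bool),
        hrv_mask,
    ])
    # rr_pre / rr_post come straight from context; mask them when unknown
    mask[len(STATISTICAL_NAMES) + 0] = rr.rr_pre is None
    mask[len(STATISTICAL_NAMES) + 1] = rr.rr_post is None
    return FeatureVector(values=values, mask=mask)
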