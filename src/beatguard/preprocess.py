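"""Signal conditioning: bandpass filtering, R-peak detection, segmentation.

The conditioning filter is a 4th-order Butterworth bandpass (0.5–40 Hz by
default), applied zero-phase (forward–backward) so fiducial timings are not
shifted; the effective magnitude response is therefore the square of the
4th-order design.  A ``causal=True`` option applies the literal single-pass
filter instead.

R-peak detection follows the canonical Pan-Tompkins recipe: a 5–15 Hz
detection bandpass, five-point derivative, squaring, 150 ms moving-window
integration, adaptive dual thresholds with search-back, and a 200 ms
refractory period.  Detection runs on the conditioned signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .records import BEAT_LEN, POST_SAMPLES, PRE_SAMPLES, BeatSegment

REFRACTORY_S = 0.200
INTEGRATION_WINDOW_S = 0.150


def bandpass_filter(x: np.ndarray, fs: float, low: float = 0.5,
                    high: float = 40.0, order: int = 4,
                    causal: bool = False) -> np.ndarray:
    """Butterworth bandpass; zero-phase by default. Length is preserved."""
    x = np.asarray(x, dtype=float)
    if not 0 < low < high < fs / 2:
        raise ValueError(
            f"band must satisfy 0 < low < high < fs/2, got ({low}, {high}) "
            f"at fs={fs}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if causal:
        return sps.sosfilt(sos, x)
    return sps.sosfiltfilt(sos, x)


def _pan_tompkins_integrated(x: np.ndarray, fs: float) -> np.ndarray:
    """Detection path: 5-15 Hz bandpass, derivative, square, MWI."""
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    f = sps.sosfiltfilt(sos, x)
    # five-point derivative (Pan-Tompkins difference kernel)
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    d = np.convolve(f, kernel[::-1], mode="same")
    sq = d * d
    w = max(1, int(round(INTEGRATION_WINDOW_S * fs)))
    return np.convolve(sq, np.ones(w) / w, mode="same")


def detect_r_peaks(x: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins R-peak detection; strictly increasing sample indices."""
    x = np.asarray(x, dtype=float)
    if x.size <= 2 * fs:
        raise ValueError("signal must be longer than 2 s for peak detection")
    if not np.any(x):
        return np.array([], dtype=int)

    mwi = _pan_tompkins_integrated(x, fs)
    refractory = int(round(REFRACTORY_S * fs))

    # candidate local maxima of the integrated signal
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return np.array([], dtype=int)

    # adaptive dual thresholds, initialized from the first 2 s (falling
    # back to the whole record when the head is silent), plus a global
    # floor so edge ripple on quiet records is never promoted to a beat
    head = mwi[: int(2 * fs)]
    head_max = float(np.max(head))
    global_max = float(np.max(mwi))
    spki = 0.25 * (head_max if head_max > 0.05 * global_max else global_max)
    npki = 0.5 * float(np.mean(head))
    floor = 0.02 * global_max
    threshold1 = max(npki + 0.25 * (spki - npki), floor)

    accepted: list[int] = []
    missed_limit = None
    last_qrs = -refractory
    rr_avg = None
    for c in cand:
        peak = mwi[c]
        is_qrs = False
        if c - last_qrs >= refractory and peak > threshold1:
            is_qrs = True
        elif (
            missed_limit is not None
            and accepted
            and c - last_qrs > missed_limit
            and peak > 0.5 * threshold1
            and c - last_qrs >= refractory
        ):
            is_qrs = True  # search-back with the lower threshold
        if is_qrs:
            spki = 0.125 * peak + 0.875 * spki
            if accepted:
                rr = c - last_qrs
                rr_avg = rr if rr_avg is None else 0.125 * rr + 0.875 * rr_avg
                missed_limit = int(1.66 * rr_avg)
            accepted.append(int(c))
            last_qrs = c
        else:
            npki = 0.125 * peak + 0.875 * npki
        threshold1 = max(npki + 0.25 * (spki - npki), floor)

    # refine: snap each detection to the local |signal| maximum nearby
    half = int(round(0.075 * fs))
    refined = []
    for c in accepted:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    refined = sorted(set(refined))

    # enforce the refractory period after refinement
    out: list[int] = []
    for r in refined:
        if out and r - out[-1] < refractory:
            if abs(x[r]) > abs(x[out[-1]]):
                out[-1] = r
            continue
        out.append(r)
    return np.array(out, dtype=int)


@dataclass
class SegmentationResult:
    beats: list[BeatSegment]
    dropped: int


def segment_beats(x: np.ndarray, r_peaks: np.ndarray, fs: float,
                  pre: int = PRE_SAMPLES, post: int = POST_SAMPLES,
                  record_id: str = "") -> SegmentationResult:
    """Cut fixed 256-sample windows around R-peaks.

    Windows are half-open ``[r - pre, r + post)``; beats whose window would
    cross a record boundary are dropped and counted.
    """
    if pre + post != BEAT_LEN:
        raise ValueError(f"pre + post must equal {BEAT_LEN}")
    x = np.asarray(x, dtype=float)
    beats: list[BeatSegment] = []
    dropped = 0
    for k, r in enumerate(np.asarray(r_peaks, dtype=int)):
        lo, hi = r - pre, r + post
        if lo < 0 or hi > x.size:
            dropped += 1
            continue
        beats.append(
            BeatSegment(x[lo:hi], fs, r_index=pre,
                        record_id=record_id, ordinal=k)
        )
    return SegmentationResult(beats, dropped)
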