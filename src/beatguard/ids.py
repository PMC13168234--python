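"""Signal-integrity intrusion detection and the trust gate.

The monitor works on fixed analysis windows (2 s, hop 1 s by default) and
summarizes each window with nine integrity features chosen to expose the
three in-scope threat families: spectral shape (entropy, out-of-band power
fractions) for noise injection and temporal distortion; a replay indicator
(maximum normalized cross-correlation against a trailing buffer of recent
windows) for verbatim copies; flatline and clipping fractions for
DoS-style disruption; RR-implausibility counts and a device message
counter for rhythm- and transport-level anomalies.

A binary gradient-boosted classifier turns the window features into an
attack probability ``p_attack``; the trust score is ``T = 1 − p_attack``
and the inference is flagged untrusted exactly when ``T < τ``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skm

from .io import ModelBundle
from .model import Hyperparams, LabeledFeatures, predict_proba, train
from .records import ECGRecord
from .synth import AttackScenario, RhythmSpec, inject_attack, synth_record

IDS_FEATURE_NAMES = (
    "spectral_entropy",
    "low_band_fraction",     # power below 0.5 Hz
    "high_band_fraction",    # power above 40 Hz
    "amplitude_kurtosis",
    "clipping_fraction",
    "rr_implausibility",     # count of RR < 200 ms or > 3000 ms
    "replay_correlation",    # max correlation vs trailing window buffer
    "flatline_fraction",
    "message_rate",          # device counter proxy (messages per window)
    "tempo_deviation",       # |window RR median - running RR median| ratio
)

WINDOW_S = 2.0
HOP_S = 1.0
REPLAY_BUFFER = 5

IDS_CLASSES = ("clean", "attack")


@dataclass(frozen=True)
class TrustAssessment:
    """Attack probability, trust score, threshold and gate decision."""

    p_attack: float
    trust: float
    tau: float
    flag: str

    @property
    def trusted(self) -> bool:
        return self.flag == "trusted"


def trust_assess(p_attack: float, tau: float = 0.5) -> TrustAssessment:
    """Trust score T = 1 − p_attack; untrusted exactly when T < τ."""
    if not 0.0 <= p_attack <= 1.0:
        raise ValueError("p_attack must lie in [0, 1]")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    trust = 1.0 - p_attack
    return TrustAssessment(
        p_attack=p_attack,
        trust=trust,
        tau=tau,
        flag="untrusted" if trust < tau else "trusted",
    )


def _spectral_features(x: np.ndarray, fs: float) -> tuple[float, float, float]:
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    power = np.abs(np.fft.rfft(x - np.mean(x))) ** 2
    total = float(np.sum(power))
    if total == 0.0:
        return 0.0, 0.0, 0.0
    p = power / total
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)) / np.log2(p.size))
    low = float(np.sum(p[freqs < 0.5]))
    high = float(np.sum(p[freqs > 40.0]))
    return entropy, low, high


def integrity_features(window: np.ndarray, fs: float,
                       rr_ms: np.ndarray | None = None,
                       buffer: list[np.ndarray] | None = None,
                       message_count: int | None = None,
                       clip_level: float | None = None,
                       rr_baseline_ms: float | None = None) -> np.ndarray:
    """The integrity features for one analysis window.

    ``rr_ms`` are the RR intervals whose beats fall in the window;
    ``buffer`` holds the most recent clean-side windows for the replay
    indicator; ``message_count`` is the device counter proxy (defaults to
    the nominal one message per window); ``rr_baseline_ms`` is the
    device's running RR median, against which the window's tempo is
    compared (temporal-distortion and foreign-rhythm indicator).
    """
    x = np.asarray(window, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("integrity window must span at least 2 s")
    entropy, low, high = _spectral_features(x, fs)

    sd = float(np.std(x))
    if sd == 0.0:
        kurt = 0.0
    else:
        z = (x - np.mean(x)) / sd
        kurt = float(np.mean(z**4) - 3.0)

    # saturation rail: well above physiologic mV range, so clean ECG never
    # clips; ADC-saturating injections do
    level = 3.0 if clip_level is None else clip_level
    clipping = float(np.mean(np.abs(x) >= level)) if level > 0 else 0.0

    rr_bad = 0.0
    if rr_ms is not None and len(rr_ms):
        rr = np.asarray(rr_ms, dtype=float)
        rr_bad = float(np.sum((rr < 200.0) | (rr > 3000.0)))

    corr = 0.0
    if buffer:
        for past in buffer[-REPLAY_BUFFER:]:
            m = min(past.size, x.size)
            a, b = x[:m], past[:m]
            if np.std(a) > 0 and np.std(b) > 0:
                corr = max(corr, float(np.corrcoef(a, b)[0, 1]))

    # a flat channel repeats samples exactly (DoS/flatline); genuine ECG
    # baselines drift at float precision and never do
    flat = float(np.mean(np.diff(x) == 0.0))

    msgs = float(message_count if message_count is not None else 1.0)

    tempo = 0.0
    if (rr_baseline_ms is not None and rr_baseline_ms > 0
            and rr_ms is not None and len(rr_ms)):
        med = float(np.median(np.asarray(rr_ms, dtype=float)))
        tempo = abs(med - rr_baseline_ms) / rr_baseline_ms

    return np.array([entropy, low, high, kurt, clipping,
                     rr_bad, corr, flat, msgs, tempo])


def window_record(record: ECGRecord, window_s: float = WINDOW_S,
                  hop_s: float = HOP_S) -> list[tuple[int, int]]:
    """Half-open (start, stop) sample spans of the analysis windows."""
    n = record.samples.size
    w = int(round(window_s * record.fs))
    h = int(round(hop_s * record.fs))
    return [(i, i + w) for i in range(0, n - w + 1, h)]


def record_window_features(record: ECGRecord,
                           window_s: float = WINDOW_S,
                           hop_s: float = HOP_S) -> np.ndarray:
    """Integrity features for every analysis window of a record.

    Beats are re-detected from the incoming signal (annotations cannot be
    trusted on a possibly tampered stream).  The replay buffer holds the
    preceding ``REPLAY_BUFFER`` windows; the tempo baseline is the running
    median of all RR intervals observed before the current window.
    """
    from .preprocess import bandpass_filter, detect_r_peaks

    spans = window_record(record, window_s, hop_s)
    fs = record.fs
    try:
        filtered = bandpass_filter(record.samples, fs)
        r_idx = detect_r_peaks(filtered, fs)
    except ValueError:
        r_idx = np.empty(0, dtype=int)
    rr = np.diff(r_idx) / fs * 1000.0 if r_idx.size > 1 else np.empty(0)
    rr_end = r_idx[1:] if r_idx.size > 1 else np.empty(0, dtype=int)
    rows = []
    buffer: list[np.ndarray] = []
    for lo, hi in spans:
        w = record.samples[lo:hi]
        in_win = (rr_end >= lo) & (rr_end < hi)
        past = rr[rr_end < lo]
        baseline = float(np.median(past)) if past.size >= 4 else None
        rows.append(integrity_features(
            w, fs,
            rr_ms=rr[in_win] if rr.size else None,
            buffer=buffer,
            rr_baseline_ms=baseline,
        ))
        buffer.append(w.copy())
        if len(buffer) > REPLAY_BUFFER:
            buffer.pop(0)
    return np.array(rows)


def window_labels(record: ECGRecord, mask: np.ndarray,
                  window_s: float = WINDOW_S, hop_s: float = HOP_S,
                  overlap: float = 0.5) -> np.ndarray:
    """Label windows as attacked when ≥ ``overlap`` of their samples are."""
    spans = window_record(record, window_s, hop_s)
    return np.array([
        float(np.mean(mask[lo:hi])) >= overlap for lo, hi in spans
    ])


def train_ids(clean_windows: np.ndarray, attacked_windows: np.ndarray,
              hp: Hyperparams | None = None) -> ModelBundle:
    """Binary attack-probability classifier over integrity features."""
    if len(clean_windows) == 0 or len(attacked_windows) == 0:
        raise ValueError("both clean and attacked windows are required")
    X = np.concatenate([clean_windows, attacked_windows])
    y = ([IDS_CLASSES[0]] * len(clean_windows)
         + [IDS_CLASSES[1]] * len(attacked_windows))
    hp = hp or Hyperparams(n_estimators=300, max_depth=6, num_leaves=31)
    features = LabeledFeatures(X, y, list(IDS_FEATURE_NAMES),
                               provenance="ids-windows")
    return train(features, hp, apply_smote=False)


def attack_probability(bundle: ModelBundle, windows: np.ndarray) -> np.ndarray:
    probs = predict_proba(bundle, np.atleast_2d(windows))
    return probs[:, bundle.classes.index(IDS_CLASSES[1])]


def ids_metrics(y_true: np.ndarray, p_attack: np.ndarray,
                tau: float = 0.5) -> dict[str, float]:
    """The IDS metric battery at operating threshold τ.

    A window is flagged (predicted attack) when trust ``1 − p < τ``,
    i.e. when ``p > 1 − τ``.
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(p_attack, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("ids_metrics requires both classes in y_true")
    pred = (p > 1.0 - tau).astype(int)
    tn, fp, fn, tp = skm.confusion_matrix(y, pred, labels=[0, 1]).ravel()
    return {
        "precision": float(skm.precision_score(y, pred, zero_division=0)),
        "recall": float(skm.recall_score(y, pred, zero_division=0)),
        "f1": float(skm.f1_score(y, pred, zero_division=0)),
        "roc_auc": float(skm.roc_auc_score(y, p)),
        "pr_auc": float(skm.average_precision_score(y, p)),
        "fpr": float(fp / (fp + tn)) if fp + tn else 0.0,
        "fnr": float(fn / (fn + tp)) if fn + tp else 0.0,
        "mcc": float(skm.matthews_corrcoef(y, pred)),
        "brier": float(np.mean((p - y) ** 2)),
        "tau": float(tau),
    }


def tau_sweep(y_true: np.ndarray, p_attack: np.ndarray,
              taus: np.ndarray | None = None) -> list[dict[str, float]]:
    """Sensitivity sweep of the trust threshold."""
    taus = np.linspace(0.1, 0.9, 9) if taus is None else np.asarray(taus)
    return [ids_metrics(y_true, p_attack, float(t)) for t in taus]


def build_attack_benchmark(
    n_records: int = 8,
    intensity: float = 0.8,
    seed: int = 0,
    duration: float = 60.0,
    attack_types: tuple[str, ...] | None = None,
) -> dict[str, np.ndarray]:
    """Desk-scale benchmark: clean vs attacked window features per threat.

    Each record gets one attacked span covering its middle third; clean
    windows come from unattacked copies of the same rhythms.
    """
    from .synth import ATTACK_TYPES

    attack_types = attack_types or ATTACK_TYPES
    rng = np.random.default_rng(seed)
    clean_rows, attack_rows, attack_kinds = [], [], []
    for i in range(n_records):
        spec = RhythmSpec(
            mean_hr_bpm=float(rng.uniform(60, 90)),
            rr_jitter_sd=0.03,
            pvc_probability=0.0,
            duration=duration,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, _ = synth_record(spec)
        clean_rows.append(record_window_features(rec))
        for atype in attack_types:
            scen = AttackScenario(
                type=atype, intensity=intensity,
                start=duration / 3.0, end=2.0 * duration / 3.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            attacked, mask = inject_attack(rec, scen)
            feats = record_window_features(attacked)
            labels = window_labels(attacked, mask)
            attack_rows.append(feats[labels])
            attack_kinds.extend([atype] * int(labels.sum()))
    return {
        "clean": np.concatenate(clean_rows),
        "attacked": np.concatenate(attack_rows),
        "attack_types": np.array(attack_kinds),
    }
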