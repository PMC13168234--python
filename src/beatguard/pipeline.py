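"""Record-level glue: conditioning, segmentation and feature tables.

``features_from_record`` turns one annotated (or raw) record into the
canonical feature table used for training and evaluation: one row per
beat — ``beat_id, record_id, label`` followed by the 40 canonical feature
columns, with NaN marking masked values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, extract_features
from .preprocess import bandpass_filter, detect_r_peaks, segment_beats
from .records import BEAT_LABELS, ECGRecord, RRContext

#: Trailing RR-history window (beats) feeding the HRV feature group.
RR_HISTORY_LEN = 32


def rr_contexts(r_indices: np.ndarray, fs: float,
                history_len: int = RR_HISTORY_LEN) -> list[RRContext]:
    """Per-beat RR context (ms) from an ordered R-peak index array."""
    r = np.asarray(r_indices, dtype=float)
    rr_ms = np.diff(r) / fs * 1000.0
    out = []
    for i in range(r.size):
        pre = rr_ms[i - 1] if i >= 1 else None
        post = rr_ms[i] if i < rr_ms.size else None
        hist = rr_ms[max(0, i - history_len):i]
        out.append(RRContext(rr_pre=pre, rr_post=post, rr_history=hist))
    return out


def features_from_record(record: ECGRecord, use_annotations: bool = True,
                         filter_signal: bool = True,
                         drop_other: bool = True) -> pd.DataFrame:
    """Extract the per-beat feature table from one record.

    With ``use_annotations`` the annotated R indices (and labels) anchor the
    beats; otherwise Pan-Tompkins detection runs on the conditioned signal
    and labels are empty.  Beats labeled OTHER are excluded from modeling.
    """
    x = bandpass_filter(record.samples, record.fs) if filter_signal \
        else record.samples
    if use_annotations and record.annotations:
        r_idx = record.r_indices()
        labels = record.labels()
    else:
        r_idx = detect_r_peaks(x, record.fs)
        labels = [""] * r_idx.size

    contexts = rr_contexts(r_idx, record.fs)
    seg = segment_beats(x, r_idx, record.fs, record_id=record.record_id)

    rows = []
    for beat in seg.beats:
        k = beat.ordinal
        label = labels[k]
        if drop_other and label and label not in BEAT_LABELS:
            continue
        fv = extract_features(beat, contexts[k])
        row = {
            "beat_id": f"{record.record_id}:{k}",
            "record_id": record.record_id,
            "label": label,
        }
        row.update({
            n: (np.nan if m else v)
            for n, v, m in zip(FEATURE_NAMES, fv.values, fv.mask)
        })
        rows.append(row)
    cols = ["beat_id", "record_id", "label", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols)


def features_from_records(records: list[ECGRecord], **kwargs) -> pd.DataFrame:
    tables = [features_from_record(r, **kwargs) for r in records]
    return pd.concat(tables, ignore_index=True) if tables \
        else pd.DataFrame(columns=["beat_id", "record_id", "label",
                                   *FEATURE_NAMES])


def table_to_labeled(table: pd.DataFrame):
    """Feature table → (X, y) arrays in canonical column order."""
    from .model import LabeledFeatures

    X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = table["label"].astype(str).tolist()
    return LabeledFeatures(X, y, list(FEATURE_NAMES),
                           provenance="feature-table")
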