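"""Reading and writing ECG records, beat tables, feature tables and models.

WFDB support covers the subset the MIT-BIH arrhythmia layout actually uses:
a plain-text header (``.hea``), signal data in format 212 (two 12-bit
two's-complement samples packed into 3 bytes) or format 16 (little-endian
int16), and the MIT binary annotation format (``.atr``).  Amplitudes are
converted to millivolts with the header's gain/baseline.

Model bundles are self-describing JSON documents embedding the LightGBM
tree dump as portable text, never a binary pickle.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .records import (
    BEAT_LEN,
    BeatAnnotation,
    BeatSegment,
    ECGRecord,
    map_symbol,
)

BUNDLE_VERSION = 1

# MIT annotation codes for the modeled beat types (standard code table).
_LABEL_TO_CODE = {"N": 1, "L": 2, "R": 3, "V": 5, "A": 8, "OTHER": 13}
_CODE_TO_SYMBOL = {1: "N", 2: "L", 3: "R", 5: "V", 8: "A"}
_SKIP_CODE = 59


class FormatError(ValueError):
    """Unsupported or malformed on-disk format."""


class SchemaError(ValueError):
    """Tabular input does not match the expected schema."""


class BundleError(ValueError):
    """Model bundle is invalid or incompatible."""


# ---------------------------------------------------------------------------
# format-212 packing
# ---------------------------------------------------------------------------

def encode_212(samples: np.ndarray) -> bytes:
    """Pack 12-bit two's-complement sample pairs into 3-byte blocks."""
    s = np.asarray(samples, dtype=int)
    if np.any(s < -2048) or np.any(s > 2047):
        raise FormatError("sample out of 12-bit range for format 212")
    if s.size % 2:  # pad with a trailing zero sample, dropped on read
        s = np.concatenate([s, [0]])
    u = np.where(s < 0, s + 4096, s).astype(np.uint16)
    a, b = u[0::2], u[1::2]
    out = np.empty(3 * a.size, dtype=np.uint8)
    out[0::3] = a & 0xFF
    out[1::3] = ((a >> 8) & 0x0F) | (((b >> 8) & 0x0F) << 4)
    out[2::3] = b & 0xFF
    return out.tobytes()


def decode_212(data: bytes, n_samples: int) -> np.ndarray:
    """Unpack ``n_samples`` 12-bit samples from 3-byte format-212 blocks."""
    raw = np.frombuffer(data, dtype=np.uint8)
    if raw.size % 3:
        raise FormatError("truncated format-212 block")
    a = raw[0::3].astype(np.int32) | ((raw[1::3] & 0x0F).astype(np.int32) << 8)
    b = raw[2::3].astype(np.int32) | ((raw[1::3] >> 4).astype(np.int32) << 8)
    s = np.empty(a.size + b.size, dtype=np.int32)
    s[0::2], s[1::2] = a, b
    s = np.where(s > 2047, s - 4096, s)
    if s.size < n_samples:
        raise FormatError("format-212 data shorter than header declares")
    return s[:n_samples]


# ---------------------------------------------------------------------------
# WFDB records
# ---------------------------------------------------------------------------

def read_wfdb_record(path: str | Path) -> ECGRecord:
    """Read a WFDB record (header + signal + optional annotations).

    ``path`` is the record path without extension.  The first signal is
    taken; amplitudes are converted to mV via ``(adc - baseline) / gain``.
    """
    base = Path(path)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing header file: {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    record_id = head[0]
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0

    sig = lines[1].split()
    dat_name, fmt = sig[0], sig[1]
    fmt_code = int(fmt.split("x")[0].split(":")[0].split("+")[0])
    gain, baseline = 200.0, 0
    if len(sig) > 2:
        spec = sig[2]
        if "/" in spec:
            spec = spec.split("/")[0]
        if "(" in spec:
            gain_s, base_s = spec.split("(")
            gain = float(gain_s)
            baseline = int(base_s.rstrip(")"))
        else:
            gain = float(spec)
    if gain == 0:
        gain = 200.0
    lead = sig[-1] if len(sig) > 8 else "MLII"

    dat = base.parent / dat_name
    if not dat.exists():
        raise FileNotFoundError(f"missing signal file: {dat}")
    data = dat.read_bytes()
    if fmt_code == 212:
        adc = decode_212(data, n_samples)
    elif fmt_code == 16:
        adc = np.frombuffer(data, dtype="<i2")[:n_samples].astype(np.int32)
        if adc.size < n_samples:
            raise FormatError("format-16 data shorter than header declares")
    else:
        raise FormatError(f"unsupported WFDB signal format code {fmt_code}")
    mv = (adc.astype(float) - baseline) / gain

    atr = base.with_suffix(".atr")
    annotations = read_annotations(atr, n_samples) if atr.exists() else []
    return ECGRecord(record_id, fs, mv, lead=lead, annotations=annotations)


def write_wfdb_record(record: ECGRecord, path: str | Path, *,
                      gain: float = 200.0, baseline: int = 0,
                      fmt: int = 212) -> None:
    """Write a record in WFDB layout (header, signal, annotations)."""
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    adc = np.rint(record.samples * gain + baseline).astype(int)
    dat_name = base.stem + ".dat"
    if fmt == 212:
        payload = encode_212(adc)
    elif fmt == 16:
        payload = adc.astype("<i2").tobytes()
    else:
        raise FormatError(f"unsupported WFDB signal format code {fmt}")
    (base.parent / dat_name).write_bytes(payload)
    hea = (
        f"{base.stem} 1 {record.fs:g} {record.samples.size}\n"
        f"{dat_name} {fmt} {gain:g}({baseline})/mV 12 0 0 0 0 {record.lead}\n"
    )
    base.with_suffix(".hea").write_text(hea)
    if record.annotations:
        write_annotations(record.annotations, base.with_suffix(".atr"))


def read_annotations(path: str | Path, n_samples: int | None = None
                     ) -> list[BeatAnnotation]:
    """Read MIT-format annotations, mapping symbols onto {N,L,R,V,A,OTHER}."""
    data = Path(path).read_bytes()
    out: list[BeatAnnotation] = []
    t = 0
    i = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code, dt = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == _SKIP_CODE:
            if i + 4 > len(data):
                raise FormatError("truncated SKIP annotation")
            hi = data[i] | (data[i + 1] << 8)
            lo = data[i + 2] | (data[i + 3] << 8)
            i += 4
            t += struct.unpack(">i", struct.pack(">HH", hi, lo))[0]
            continue
        t += dt
        if code in range(1, 50):
            symbol = _CODE_TO_SYMBOL.get(code, "?")
            if n_samples is None or t < n_samples:
                out.append(BeatAnnotation(t, map_symbol(symbol)))
    return out


def write_annotations(annotations: Iterable[BeatAnnotation],
                      path: str | Path) -> None:
    buf = bytearray()
    prev = 0
    for ann in annotations:
        dt = ann.sample_index - prev
        prev = ann.sample_index
        if dt > 1023:
            buf += struct.pack("<H", _SKIP_CODE << 10)
            buf += struct.pack("<HH", (dt >> 16) & 0xFFFF, dt & 0xFFFF)
            dt = 0
        code = _LABEL_TO_CODE[ann.label]
        buf += struct.pack("<H", (code << 10) | dt)
    buf += b"\x00\x00"
    Path(path).write_bytes(bytes(buf))


# ---------------------------------------------------------------------------
# Beat and feature tables
# ---------------------------------------------------------------------------

def read_beat_csv(path: str | Path, fs: float = 360.0
                  ) -> list[tuple[BeatSegment, str]]:
    """Read a beat table: one beat per row, 256 sample columns + ``label``."""
    df = pd.read_csv(path)
    sample_cols = [c for c in df.columns if c != "label"]
    if "label" not in df.columns or len(sample_cols) != BEAT_LEN:
        raise SchemaError(
            f"expected {BEAT_LEN} sample columns plus a label column, "
            f"found {len(sample_cols)} sample columns"
        )
    labels = df["label"].astype(str).tolist()
    mat = df[sample_cols].to_numpy(dtype=float)
    return [
        (BeatSegment(mat[i], fs, ordinal=i), labels[i])
        for i in range(len(df))
    ]


def write_beat_csv(beats: Iterable[tuple[BeatSegment, str]],
                   path: str | Path) -> None:
    rows = [list(seg.samples) + [label] for seg, label in beats]
    cols = [f"s{i}" for i in range(BEAT_LEN)] + ["label"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_feature_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Model bundles
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """A trained tree ensemble plus everything needed to reuse it.

    The booster is stored as LightGBM's portable text dump, so bundles are
    diffable and round-trip bit-identically through save/load.
    """

    booster_text: str
    feature_names: list[str]
    classes: list[str]
    hyperparams: dict
    seed: int
    metadata: dict = field(default_factory=dict)
    version: int = BUNDLE_VERSION

    _booster: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.booster_text:
            raise BundleError("empty booster dump")
        n = self.booster().num_feature()
        if len(self.feature_names) != n:
            raise BundleError(
                f"feature name list length {len(self.feature_names)} does not "
                f"match model descriptor length {n}"
            )
        if len(self.classes) < 2:
            raise BundleError("a bundle must carry at least two classes")

    def booster(self):
        if self._booster is None:
            import lightgbm as lgb

            self._booster = lgb.Booster(model_str=self.booster_text)
        return self._booster


def save_model(bundle: ModelBundle, path: str | Path) -> None:
    doc = {
        "format": "beatguard-model-bundle",
        "version": bundle.version,
        "feature_names": bundle.feature_names,
        "classes": bundle.classes,
        "hyperparams": bundle.hyperparams,
        "seed": bundle.seed,
        "metadata": bundle.metadata,
        "booster_text": bundle.booster_text,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_model(path: str | Path) -> ModelBundle:
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise BundleError(f"cannot parse model bundle {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != "beatguard-model-bundle":
        raise BundleError(f"{path} is not a beatguard model bundle")
    if doc.get("version") != BUNDLE_VERSION:
        raise BundleError(
            f"bundle version {doc.get('version')} is incompatible with "
            f"supported version {BUNDLE_VERSION}"
        )
    return ModelBundle(
        booster_text=doc["booster_text"],
        feature_names=list(doc["feature_names"]),
        classes=list(doc["classes"]),
        hyperparams=dict(doc["hyperparams"]),
        seed=int(doc["seed"]),
        metadata=dict(doc.get("metadata", {})),
        version=int(doc["version"]),
    )
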