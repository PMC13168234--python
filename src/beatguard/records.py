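"""Core ECG containers shared across the pipeline.

The class universe is the five MIT-BIH beat types evaluated throughout the
package: Normal (N), left/right bundle branch block (L, R), premature
ventricular contraction (V) and atrial premature contraction (A). Any other
annotation symbol maps to ``OTHER`` and is excluded from modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Beat labels used for training and evaluation, in canonical order.
BEAT_LABELS: tuple[str, ...] = ("N", "L", "R", "V", "A")

#: Sentinel for annotation symbols outside the modeled class universe.
OTHER_LABEL = "OTHER"

#: Default beat window geometry: samples kept before/after the R-peak.
PRE_SAMPLES = 100
POST_SAMPLES = 156
BEAT_LEN = PRE_SAMPLES + POST_SAMPLES  # 256


def map_symbol(symbol: str) -> str:
    """Map an annotation symbol onto the closed label set (total mapping)."""
    return symbol if symbol in BEAT_LABELS else OTHER_LABEL


@dataclass(frozen=True)
class BeatAnnotation:
    """An R-peak location plus its beat label."""

    sample_index: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in BEAT_LABELS + (OTHER_LABEL,):
            raise ValueError(f"unknown beat label {self.label!r}")
        if self.sample_index < 0:
            raise ValueError("sample_index must be non-negative")


@dataclass
class ECGRecord:
    """A single-lead ECG record in millivolts with beat annotations."""

    record_id: str
    fs: float
    samples: np.ndarray
    lead: str = "MLII"
    annotations: list[BeatAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a nonempty 1-D sequence")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        idx = [a.sample_index for a in self.annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotation indices must be strictly increasing")
        if idx and idx[-1] >= self.samples.size:
            raise ValueError("annotation index beyond end of record")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def r_indices(self) -> np.ndarray:
        return np.array([a.sample_index for a in self.annotations], dtype=int)

    def labels(self) -> list[str]:
        return [a.label for a in self.annotations]


@dataclass
class BeatSegment:
    """A windowed beat anchored on its R-peak (256 samples in the pipeline).

    ``r_index`` is the position of the anchoring R-peak inside the window
    (100 under default segmentation; windows are half-open
    ``[r - pre, r + post)`` in record coordinates).  The container itself
    accepts any window of at least 64 samples so the generator can render
    beats at other sizes; segmentation and feature extraction enforce the
    canonical 256-sample geometry.
    """

    samples: np.ndarray
    fs: float
    r_index: int = PRE_SAMPLES
    record_id: str = ""
    ordinal: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 64:
            raise ValueError(
                f"beat window must hold at least 64 samples, "
                f"got {self.samples.size}"
            )
        if not 0 <= self.r_index < self.samples.size:
            raise ValueError("r_index outside the window")
        if not self.fs > 0:
            raise ValueError("fs must be positive")


@dataclass
class RRContext:
    """Pre/post RR intervals and a trailing RR history, all in ms."""

    rr_pre: float | None
    rr_post: float | None
    rr_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.rr_history = np.asarray(self.rr_history, dtype=float)
        for rr in (self.rr_pre, self.rr_post):
            if rr is not None and not rr > 0:
                raise ValueError("RR intervals must be positive")
        if self.rr_history.size and not np.all(self.rr_history > 0):
            raise ValueError("RR history entries must be positive")
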