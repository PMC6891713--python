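"""Block segmentation, hierarchical labeling and frequency reduction.

A *block* is a fixed-width window of consecutive triaxial samples carrying a
single class label; it is the unit the classifier sees.  Blocks are cut with
a stride (default 50% of the width) and labeled by the share of the most
relevant class present: FALL if the FALL fraction reaches ``fall_frac``,
else ALERT if the ALERT fraction reaches ``alert_frac``, else BKG.  The
relevance order FALL > ALERT > BKG means a tie on both thresholds resolves
to FALL.

Reduced-frequency variants are produced by decimation: dropping the samples
in even (1-based) position halves the width and the effective sampling rate
while leaving the label unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .synthdata import CLASSES, Recording

logger = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    """Window width (samples), stride as a fraction of the width, and the
    two labeling thresholds.

    Defaults: width 256 (1.28 s at 200 Hz), 50% stride, FALL threshold
    12.5% (=> at least 160 ms of impact content at 200 Hz), ALERT threshold
    50% (=> at least 640 ms of hazard content).
    """

    width: int = 256
    stride_fraction: float = 0.5
    fall_frac: float = 0.125
    alert_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ValueError("width must be >= 2")
        if not 0 < self.stride_fraction <= 1:
            raise ValueError("stride_fraction must be in (0, 1]")
        if self.stride < 1:
            raise ValueError("stride floor(width * stride_fraction) must be >= 1")
        for name in ("fall_frac", "alert_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    @property
    def stride(self) -> int:
        return int(self.width * self.stride_fraction)


@dataclass
class Block:
    """Fixed-width window with one class label and provenance."""

    values: np.ndarray  # (width, 3)
    label: str
    recording_id: str
    start_index: int
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError(f"block values must be (width, 3), got {self.values.shape}")
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")
        if self.start_index < 0:
            raise ValueError("start_index must be non-negative")

    @property
    def width(self) -> int:
        return len(self.values)


def label_block(sample_labels: Sequence[str], cfg: SegmentationConfig) -> str:
    """Label a window by the fraction of its most relevant class.

    FALL if fraction(FALL) >= cfg.fall_frac, else ALERT if
    fraction(ALERT) >= cfg.alert_frac, else BKG.  Comparisons are inclusive.
    """
    labels = np.asarray(sample_labels, dtype="<U5")
    if len(labels) != cfg.width:
        raise ValueError(f"expected {cfg.width} sample labels, got {len(labels)}")
    unknown = set(np.unique(labels)) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    n = len(labels)
    if np.count_nonzero(labels == "FALL") / n >= cfg.fall_frac:
        return "FALL"
    if np.count_nonzero(labels == "ALERT") / n >= cfg.alert_frac:
        return "ALERT"
    return "BKG"


def segment(recording: Recording, cfg: SegmentationConfig | None = None) -> list[Block]:
    """Cut a recording into overlapping labeled blocks.

    Blocks start at 0, s, 2s, ... with s = floor(width * stride_fraction);
    trailing samples that cannot fill a block are dropped.  A recording
    shorter than one width yields an empty list (with a warning).
    """
    cfg = cfg or SegmentationConfig()
    T = len(recording)
    if T < cfg.width:
        logger.warning(
            "recording %s has %d samples < width %d; no blocks produced",
            recording.recording_id,
            T,
            cfg.width,
        )
        return []
    s = cfg.stride
    blocks = []
    for start in range(0, T - cfg.width + 1, s):
        window = slice(start, start + cfg.width)
        blocks.append(
            Block(
                values=recording.samples[window],
                label=label_block(recording.labels[window], cfg),
                recording_id=recording.recording_id,
                start_index=start,
                sample_rate_hz=recording.sample_rate_hz,
            )
        )
    return blocks


def decimate(block: Block) -> Block:
    """Halve a block's width and rate by dropping even-position samples.

    Positions are 1-based, so the window's first sample is always retained
    (rows 0, 2, 4, ... survive).  The label is unchanged.
    """
    if block.width % 2 != 0:
        raise ValueError(f"cannot decimate odd width {block.width}")
    return replace(
        block,
        values=block.values[0::2],
        sample_rate_hz=block.sample_rate_hz / 2,
    )


def build_block_datasets(
    recordings: Iterable[Recording] | Mapping[str, list[Recording]],
    cfg: SegmentationConfig | None = None,
    levels: int = 3,
) -> list[list[Block]]:
    """Segment once, then produce ``levels`` successively decimated copies.

    Level 0 is the segmented dataset at the native rate; level k halves the
    width and rate of level k-1.  All levels share block counts, labels and
    provenance.
    """
    cfg = cfg or SegmentationConfig()
    if levels < 0:
        raise ValueError("levels must be >= 0")
    if cfg.width % (2**levels) != 0:
        raise ValueError(f"width {cfg.width} is not divisible by 2^{levels}")
    if isinstance(recordings, Mapping):
        recordings = [r for recs in recordings.values() for r in recs]
    level0: list[Block] = []
    for rec in recordings:
        level0.extend(segment(rec, cfg))
    datasets = [level0]
    for _ in range(levels):
        datasets.append([decimate(b) for b in datasets[-1]])
    return datasets


def blocks_to_arrays(blocks: Sequence[Block]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack blocks into (X, y, recording_ids) arrays for the estimators."""
    if not blocks:
        raise ValueError("no blocks given")
    X = np.stack([b.values for b in blocks])
    y = np.array([b.label for b in blocks], dtype="<U5")
    rec_ids = np.array([b.recording_id for b in blocks])
    return X, y, rec_ids


class Decimator(TransformerMixin, BaseEstimator):
    """sklearn-style transformer applying ``levels`` decimation steps to a
    stacked block array of shape (n_blocks, width, 3)."""

    def __init__(self, levels: int = 1):
        self.levels = levels

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("expected (n_blocks, width, 3) array")
        if X.shape[1] % (2**self.levels) != 0:
            raise ValueError(f"width {X.shape[1]} not divisible by 2^{self.levels}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X)
        for _ in range(self.levels):
            X = X[:, 0::2, :]
        return X
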