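"""Lightweight in-memory containers shared across pipeline stages.

Trial tables are plain :class:`pandas.DataFrame` objects (one row per
subject x item); the classes here wrap the array-valued objects that do
not fit naturally in a flat table: per-item embedding matrices, per-trial
voxel patterns, ROI time series with condition blocks, and stacks of
connectivity matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

__all__ = [
    "ModelEmbedding",
    "PatternSet",
    "TimeSeriesSet",
    "ConnectivityStack",
]

TIMEPOINTS = ("pre", "post")
CONDITIONS = ("HI", "LO")


@dataclass
class ModelEmbedding:
    """Per-item embedding vectors standing in for a conceptual model.

    Parameters
    ----------
    name:
        Model label, e.g. ``"image_model"`` (a CNN-penultimate-layer
        stand-in) or ``"word_model"`` (a word-embedding stand-in).
    item_ids:
        Item identifiers, one per row of ``vectors``.
    vectors:
        ``(n_items, dim)`` array; rows are the item embeddings.
    """

    name: str
    item_ids: np.ndarray
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.item_ids = np.asarray(self.item_ids)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be 2-D (items x dim)")
        if len(self.item_ids) != self.vectors.shape[0]:
            raise ValueError("item_ids and vectors row count differ")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector_for(self, item_id) -> np.ndarray:
        idx = np.flatnonzero(self.item_ids == item_id)
        if idx.size == 0:
            raise KeyError(f"item {item_id!r} not in embedding {self.name!r}")
        return self.vectors[idx[0]]


@dataclass
class PatternSet:
    """Per (subject, ROI, timepoint) item-by-voxel activation patterns.

    ``data`` maps ``(subject_id, roi, timepoint)`` to a DataFrame whose
    index holds item ids and whose columns are voxels. Items without an
    event at a timepoint are simply absent from that frame (never
    zero-filled).
    """

    data: dict = field(default_factory=dict)

    def add(self, subject, roi: str, timepoint: str, patterns: pd.DataFrame) -> None:
        if timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        self.data[(subject, roi, timepoint)] = patterns

    def get(self, subject, roi: str, timepoint: str) -> pd.DataFrame:
        return self.data[(subject, roi, timepoint)]

    @property
    def subjects(self) -> list:
        return sorted({k[0] for k in self.data})

    @property
    def rois(self) -> list[str]:
        return sorted({k[1] for k in self.data})

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class TimeSeriesSet:
    """ROI time series per (subject, run) plus the stimulus block table.

    ``data`` maps ``(subject_id, run)`` to an ``(n_rois, n_samples)``
    array sampled every ``tr`` seconds. ``blocks`` has one row per
    stimulus block with columns ``subject_id, run, item_id, onset,
    duration, condition`` (condition in ``{"HI", "LO", "unsolved"}``;
    onset/duration in seconds).
    """

    data: dict
    roi_names: list[str]
    tr: float
    blocks: pd.DataFrame

    def series(self, subject, run: int) -> np.ndarray:
        return self.data[(subject, run)]

    def block_mask(self, subject, run: int, condition: str) -> np.ndarray:
        """Boolean sample mask covering all blocks of one condition."""
        n = self.data[(subject, run)].shape[1]
        mask = np.zeros(n, dtype=bool)
        rows = self.blocks[
            (self.blocks.subject_id == subject)
            & (self.blocks.run == run)
            & (self.blocks.condition == condition)
        ]
        for onset, dur in zip(rows.onset, rows.duration):
            lo = int(np.ceil(onset / self.tr))
            hi = min(n, int(np.floor((onset + dur) / self.tr)) + 1)
            mask[lo:hi] = True
        return mask

    @property
    def subjects(self) -> list:
        return sorted({k[0] for k in self.data})

    @property
    def runs(self) -> list[int]:
        return sorted({k[1] for k in self.data})


@dataclass
class ConnectivityStack:
    """Fisher-z ROI-to-ROI matrices per subject, condition and run.

    ``z`` has shape ``(n_subjects, 2, n_runs, R, R)`` with the condition
    axis ordered (HI, LO). Missing (subject, condition, run) cells are
    all-NaN slices; the diagonal is NaN by construction.
    """

    z: np.ndarray
    subjects: list
    roi_names: list[str]
    conditions: tuple = CONDITIONS

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 5:
            raise ValueError("z must have shape (subjects, conditions, runs, R, R)")
        if self.z.shape[1] != len(self.conditions):
            raise ValueError("condition axis length mismatch")
        r = len(self.roi_names)
        if self.z.shape[-2:] != (r, r):
            raise ValueError("ROI axes do not match roi_names")

    @property
    def n_subjects(self) -> int:
        return self.z.shape[0]

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def run_average(self) -> np.ndarray:
        """Average z over runs, ignoring missing runs -> (S, 2, R, R)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.z, axis=2)
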