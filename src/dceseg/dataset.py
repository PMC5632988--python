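"""Labeled ROIs, region-mean curves, and the standardized training table.

Training supervision comes from rectangular regions of interest (ROIs) drawn
on one slice per sample, one per tissue class: tumor, vessel, normal tissue,
cavity.  For each class the voxel-wise mean raw curve over the ROI is taken,

    i_aver(t) = (1/k) * sum_j i(t, j),   j = 1..k voxels,

normalized, and described by the 7-feature vector.  With S samples and all
four classes present the table has 4*S rows.  Features are z-scored per
column with statistics computed on this table; the statistics are stored so
test-time voxels are transformed identically (no peeking).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .features import (
    FEATURE_NAMES,
    PcaBasis,
    fit_pca,
    kinetic_features_matrix,
    pca_scores_matrix,
)
from .tic import DEFAULT_CLAMP_EPS, DEFAULT_N_PRE, DynamicSeries, normalize_tics

__all__ = [
    "TissueClass",
    "CLASS_ORDER",
    "RoiRect",
    "TrainingTable",
    "mean_roi_tic",
    "build_training_table",
    "standardize",
]


class TissueClass(str, Enum):
    """The four tissue classes the cascade distinguishes."""

    TUMOR = "tumor"
    VESSEL = "vessel"
    NORMAL = "normal"
    CAVITY = "cavity"


#: Deterministic row order of classes within each sample.
CLASS_ORDER = (
    TissueClass.TUMOR,
    TissueClass.VESSEL,
    TissueClass.NORMAL,
    TissueClass.CAVITY,
)


@dataclass(frozen=True)
class RoiRect:
    """An axis-aligned rectangle on one slice: 0-based, half-open
    ``[x0, x1) x [y0, y1)``.  ``label`` is None for unlabeled search ROIs
    (the rough rectangle drawn around a lesion before segmentation)."""

    slice_index: int
    x0: int
    x1: int
    y0: int
    y1: int
    label: TissueClass | None = None

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"empty ROI rectangle: {self}")

    def validate(self, spatial_shape: tuple[int, int, int]) -> None:
        nx, ny, nz = spatial_shape
        if not (0 <= self.x0 < self.x1 <= nx and 0 <= self.y0 < self.y1 <= ny):
            raise ValueError(f"ROI {self} outside image bounds {(nx, ny)}")
        if not 0 <= self.slice_index < nz:
            raise ValueError(f"ROI slice {self.slice_index} outside {nz} slices")

    @property
    def n_voxels(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def voxel_block(self, series: DynamicSeries) -> np.ndarray:
        """The ``(n_voxels, n_frames)`` raw-trace matrix of the ROI."""
        self.validate(series.spatial_shape)
        block = series.intensities[
            self.x0 : self.x1, self.y0 : self.y1, self.slice_index, :
        ]
        return block.reshape(-1, series.n_frames)

    def to_dict(self) -> dict:
        d = {
            "slice": self.slice_index,
            "x0": self.x0,
            "x1": self.x1,
            "y0": self.y0,
            "y1": self.y1,
        }
        if self.label is not None:
            d["label"] = self.label.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RoiRect":
        label = d.get("label")
        return cls(
            slice_index=int(d["slice"]),
            x0=int(d["x0"]),
            x1=int(d["x1"]),
            y0=int(d["y0"]),
            y1=int(d["y1"]),
            label=TissueClass(label) if label is not None else None,
        )


def mean_roi_tic(series: DynamicSeries, roi: RoiRect) -> np.ndarray:
    """Voxel-wise mean raw trace over the ROI."""
    block = roi.voxel_block(series)
    if block.shape[0] == 0:
        raise ValueError("empty ROI")
    return block.mean(axis=0)


@dataclass
class TrainingTable:
    """Standardized 7-feature training rows with their class labels.

    ``features`` holds the z-scored values; ``raw_features`` the values
    before standardization; ``feature_means``/``feature_sds`` the training
    statistics used (and to be reused on any test data).
    """

    features: np.ndarray
    labels: list
    feature_means: np.ndarray
    feature_sds: np.ndarray
    raw_features: np.ndarray = field(repr=False, default=None)

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(FEATURE_NAMES))
        df["label"] = [lab.value for lab in self.labels]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def standardize(
    features: np.ndarray, means: np.ndarray, sds: np.ndarray
) -> np.ndarray:
    """Z-score ``features`` (vector or matrix rows) with stored training
    statistics: ``(x - mean) / sd`` per column."""
    return (np.asarray(features, dtype=float) - means) / sds


def _column_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    if (sds == 0).any():
        flat = [FEATURE_NAMES[i] for i in np.flatnonzero(sds == 0)]
        warnings.warn(
            f"constant feature column(s) {flat}: SD replaced by 1", stacklevel=3
        )
        sds = np.where(sds == 0, 1.0, sds)
    return means, sds


def build_training_table(
    samples,
    n_pre: int = DEFAULT_N_PRE,
    clamp_eps: float = DEFAULT_CLAMP_EPS,
) -> tuple[TrainingTable, PcaBasis]:
    """Assemble the standardized training table from labeled samples.

    Parameters
    ----------
    samples
        Iterable of ``(DynamicSeries, list[RoiRect])`` pairs.  Every sample
        must provide at least one labeled ROI per tissue class; multiple ROIs
        of one class are pooled (union of voxels) into a single mean curve.

    Returns
    -------
    (TrainingTable, PcaBasis)
        The PCA basis is fit on all normalized mean curves of this table and
        is the one frozen into the trained model.
    """
    mean_curves: list[np.ndarray] = []
    labels: list[TissueClass] = []

    n_samples = 0
    for s_idx, (series, rois) in enumerate(samples):
        n_samples += 1
        sums: dict[TissueClass, np.ndarray] = {}
        counts: dict[TissueClass, int] = {}
        for roi in rois:
            if roi.label is None:
                continue
            block = roi.voxel_block(series)
            sums[roi.label] = sums.get(roi.label, 0) + block.sum(axis=0)
            counts[roi.label] = counts.get(roi.label, 0) + block.shape[0]
        for cls in CLASS_ORDER:
            if cls not in counts:
                raise ValueError(f"sample {s_idx} is missing a {cls.value} ROI")
            mean_curves.append(sums[cls] / counts[cls])
            labels.append(cls)
    if n_samples == 0:
        raise ValueError("no samples provided")

    raw = np.asarray(mean_curves)
    values, _, _ = normalize_tics(raw, n_pre=n_pre, clamp_eps=clamp_eps)
    basis = fit_pca(values)
    K, _ = kinetic_features_matrix(values, n_pre)
    P = pca_scores_matrix(values, basis)
    X = np.hstack([K, P])

    means, sds = _column_stats(X)
    table = TrainingTable(
        features=standardize(X, means, sds),
        labels=labels,
        feature_means=means,
        feature_sds=sds,
        raw_features=X,
    )
    return table, basis
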