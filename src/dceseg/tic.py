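"""Dynamic series container and time-intensity-curve (TIC) normalization.

A DCE-MRI acquisition is a 4D array of signal intensities over ``(x, y, z, t)``
where ``t`` indexes the dynamic frames.  The trace of one voxel across frames
is its time-intensity curve.  Raw MRI intensities are scanner- and
coil-dependent, so before any feature extraction every curve is referenced to
its own pre-injection baseline:

    i_real(t) = (i_n(t) - i_pre) / i_pre

with ``i_pre`` the mean raw intensity over the frames acquired before the
contrast bolus (the first 8 frames by default).  The normalized curve is
dimensionless: 0 means "at baseline", 1 means "doubled".

The time axis throughout the package is the 1-based dynamic-frame index; the
physical frame spacing (``frame_interval_s``) is carried as metadata only and
never enters a feature formula — all rate features are ratios on the same
frame grid, so the unit cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DynamicSeries",
    "NormalizedTic",
    "extract_tic",
    "normalize_tic",
    "normalize_tics",
]

#: Default number of pre-injection frames (contrast arrives around frame 8).
DEFAULT_N_PRE = 8

#: Default relative floor for the baseline denominator.
DEFAULT_CLAMP_EPS = 1e-6


@dataclass
class DynamicSeries:
    """A 4D dynamic series indexed ``(x, y, z, t)``.

    Parameters
    ----------
    intensities
        Nonnegative, finite float array of shape ``(nx, ny, nz, n_frames)``.
    n_pre
        Number of pre-injection frames at the start of the time axis.
    frame_interval_s
        Seconds per dynamic frame.  Metadata only.
    """

    intensities: np.ndarray
    n_pre: int = DEFAULT_N_PRE
    frame_interval_s: float = 5.9

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 4:
            raise ValueError(
                f"dynamic series must be 4D (x, y, z, t); got shape {arr.shape}"
            )
        if not np.isfinite(arr).all():
            raise ValueError("dynamic series contains non-finite intensities")
        if (arr < 0).any():
            raise ValueError("dynamic series contains negative intensities")
        if not 1 <= self.n_pre < arr.shape[3]:
            raise ValueError(
                f"n_pre={self.n_pre} must satisfy 1 <= n_pre < n_frames={arr.shape[3]}"
            )
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        self.intensities = arr

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]


@dataclass
class NormalizedTic:
    """A baseline-normalized time-intensity curve.

    ``valid`` is False when the raw pre-injection baseline was at or below the
    clamp floor (near-zero signal, e.g. air in a cavity) and the denominator
    had to be replaced.
    """

    values: np.ndarray
    baseline: float
    valid: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.shape[0]


def extract_tic(series: DynamicSeries, voxel: tuple[int, int, int]) -> np.ndarray:
    """Return the raw length-``n_frames`` trace of one voxel, in frame order."""
    x, y, z = voxel
    for name, idx, size in zip(
        "xyz", (x, y, z), series.spatial_shape
    ):
        if not 0 <= idx < size:
            raise IndexError(
                f"voxel {name}-index {idx} out of bounds for axis of size {size}"
            )
    return series.intensities[x, y, z, :].copy()


def normalize_tics(
    raw: np.ndarray,
    n_pre: int = DEFAULT_N_PRE,
    clamp_eps: float = DEFAULT_CLAMP_EPS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Baseline-normalize a batch of raw curves (rows of ``raw``).

    Vectorized form of :func:`normalize_tic`.  Returns ``(values, baselines,
    valid)`` where ``values`` has the shape of ``raw``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("normalize_tics expects a 2D (n_curves, n_frames) array")
    n_frames = raw.shape[1]
    if not 1 <= n_pre < n_frames:
        raise ValueError(f"n_pre={n_pre} must satisfy 1 <= n_pre < n_frames={n_frames}")
    if clamp_eps <= 0:
        raise ValueError("clamp_eps must be positive")
    if not np.isfinite(raw).all():
        raise ValueError("raw curves contain non-finite values")

    baselines = raw[:, :n_pre].mean(axis=1)
    peaks = raw.max(axis=1)
    floor = clamp_eps * peaks
    valid = baselines >= floor
    dead = peaks <= 0  # all-zero (or nonpositive) curve: no signal at all
    valid &= ~dead
    denom = np.where(valid, baselines, np.maximum(floor, np.finfo(float).tiny))
    values = (raw - denom[:, None]) / denom[:, None]
    values[dead] = 0.0
    baselines = np.where(valid, baselines, floor)
    return values, baselines, valid


def normalize_tic(
    raw: np.ndarray,
    n_pre: int = DEFAULT_N_PRE,
    clamp_eps: float = DEFAULT_CLAMP_EPS,
) -> NormalizedTic:
    """Baseline-normalize one raw curve.

    The baseline is the mean of the first ``n_pre`` entries.  If it falls
    below ``clamp_eps * max(raw)`` it is clamped to that floor and the curve
    is flagged ``valid=False`` (an all-zero curve yields all-zero values).
    """
    raw = np.atleast_1d(np.asarray(raw, dtype=float))
    values, baselines, valid = normalize_tics(raw[None, :], n_pre, clamp_eps)
    return NormalizedTic(values=values[0], baseline=float(baselines[0]), valid=bool(valid[0]))
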