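"""Kinetic and PCA features of normalized time-intensity curves.

Five semiquantitative kinetic parameters summarize each normalized curve
``i(t)`` on the 1-based frame grid ``t = 1..T`` (``n_pre`` pre-injection
frames):

* ``i_max``   — peak normalized enhancement, ``max_t i(t)``;
* ``t_peak``  — first frame attaining the peak;
* ``t_onset`` — frames elapsed after injection until the curve first reaches
  10% of its peak: ``t_10% - n_pre`` where ``t_10%`` is the smallest
  post-injection frame with ``i(t) >= 0.1 * i_max``;
* ``wash_in`` — mean slope from the 10%-of-peak frame to the peak,
  ``(i(t_peak) - i(t_10%)) / (t_peak - t_10%)``;
* ``wash_out``— mean slope from the peak to the final frame,
  ``(i(t_peak) - i(T)) / (T - t_peak)``.

Degenerate denominators (flat curves, peak at the final frame, non-enhancing
curves with ``i_max <= 0``) map to rate 0 so classifier inputs stay finite.

Two further features are the projections of the (mean-centered) curve onto
the first two principal components of the training curves.  The PCA basis is
fit once on the training set's region-averaged curves and frozen; test voxels
are projected with the stored basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tic import NormalizedTic

__all__ = [
    "FEATURE_NAMES",
    "KineticFeatures",
    "PcaBasis",
    "FeatureVector",
    "kinetic_features",
    "kinetic_features_matrix",
    "fit_pca",
    "pca_scores",
    "feature_vector",
]

#: Fixed column order of the 7-feature vector.
FEATURE_NAMES = ("i_max", "t_peak", "t_onset", "wash_in", "wash_out", "pca_1", "pca_2")

#: Column indices of the kinetic block and the PCA block.
KINETIC_INDICES = (0, 1, 2, 3, 4)
PCA_INDICES = (5, 6)


@dataclass(frozen=True)
class KineticFeatures:
    """The five kinetic curve parameters plus the internal absolute frame
    ``t_10pct`` at which 10% of the peak is first reached."""

    i_max: float
    t_peak: int
    t_onset: int
    wash_in: float
    wash_out: float
    t_10pct: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.i_max, self.t_peak, self.t_onset, self.wash_in, self.wash_out],
            dtype=float,
        )


@dataclass
class PcaBasis:
    """Frozen PCA basis: mean curve plus the top-2 orthonormal components.

    The sign of each component is fixed so that its largest-|loading| entry is
    positive (eigenvectors are otherwise sign-ambiguous).
    """

    mean_curve: np.ndarray
    components: np.ndarray  # shape (2, n_frames)
    eigenvalues: np.ndarray  # shape (2,), descending

    def __post_init__(self) -> None:
        self.mean_curve = np.asarray(self.mean_curve, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.mean_curve.shape[0]


@dataclass(frozen=True)
class FeatureVector:
    """The 7 numbers describing one curve: 5 kinetic then 2 PCA scores."""

    kinetic: np.ndarray
    pca: np.ndarray

    @property
    def as_7(self) -> np.ndarray:
        return np.concatenate([self.kinetic, self.pca])


def _values_of(tic) -> np.ndarray:
    if isinstance(tic, NormalizedTic):
        return tic.values
    return np.asarray(tic, dtype=float)


def kinetic_features_matrix(values: np.ndarray, n_pre: int) -> tuple[np.ndarray, np.ndarray]:
    """Kinetic features for a batch of curves (rows).

    Returns ``(K, t_10pct)`` where ``K`` has columns
    (i_max, t_peak, t_onset, wash_in, wash_out).
    """
    V = np.asarray(values, dtype=float)
    if V.ndim != 2:
        raise ValueError("expected a 2D (n_curves, n_frames) array")
    if not np.isfinite(V).all():
        raise ValueError("curves contain non-finite values")
    n, T = V.shape
    if T < n_pre + 2:
        raise ValueError(f"curve length {T} too short for n_pre={n_pre}")

    i_max = V.max(axis=1)
    t_peak = V.argmax(axis=1) + 1  # first frame attaining the max, 1-based

    # first post-injection frame reaching 10% of peak
    hit = V[:, n_pre:] >= 0.1 * i_max[:, None]
    has_hit = hit.any(axis=1)
    t_10 = np.where(has_hit, hit.argmax(axis=1) + n_pre + 1, t_peak)
    t_10 = np.where(i_max > 0, t_10, t_peak)  # threshold meaningless without enhancement

    t_onset = t_10 - n_pre
    rows = np.arange(n)
    v_peak = V[rows, t_peak - 1]
    v_10 = V[rows, t_10 - 1]

    d_in = t_peak - t_10
    wash_in = np.where(d_in != 0, (v_peak - v_10) / np.where(d_in == 0, 1, d_in), 0.0)
    wash_in = np.where(i_max > 0, wash_in, 0.0)
    d_out = T - t_peak
    wash_out = np.where(d_out != 0, (v_peak - V[:, -1]) / np.where(d_out == 0, 1, d_out), 0.0)

    K = np.column_stack([i_max, t_peak.astype(float), t_onset.astype(float), wash_in, wash_out])
    return K, t_10


def kinetic_features(tic, n_pre: int) -> KineticFeatures:
    """Kinetic features of a single normalized curve."""
    values = _values_of(tic)
    K, t_10 = kinetic_features_matrix(values[None, :], n_pre)
    i_max, t_peak, t_onset, wash_in, wash_out = K[0]
    return KineticFeatures(
        i_max=float(i_max),
        t_peak=int(t_peak),
        t_onset=int(t_onset),
        wash_in=float(wash_in),
        wash_out=float(wash_out),
        t_10pct=int(t_10[0]),
    )


def fit_pca(training_tics) -> PcaBasis:
    """Fit the frozen 2-component PCA basis on a set of training curves.

    Curves are mean-centered; the components are the top-2 eigenvectors of
    the sample covariance (ddof=1), each sign-fixed so that its
    largest-|loading| entry is positive.
    """
    curves = np.asarray([_values_of(t) for t in training_tics], dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 3:
        raise ValueError("PCA requires at least 3 training curves of equal length")
    X = curves - curves.mean(axis=0)
    cov = X.T @ X / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:2]
    components = eigvec[:, order].T
    eigenvalues = np.clip(eigval[order], 0.0, None)
    for c in components:
        if c[np.argmax(np.abs(c))] < 0:
            c *= -1.0
    return PcaBasis(
        mean_curve=curves.mean(axis=0),
        components=components,
        eigenvalues=eigenvalues,
    )


def pca_scores(tic, basis: PcaBasis) -> np.ndarray:
    """Project one curve onto the basis: dot products of the mean-centered
    curve with each component."""
    values = _values_of(tic)
    if values.shape[0] != basis.n_frames:
        raise ValueError(
            f"curve length {values.shape[0]} != basis length {basis.n_frames}"
        )
    return (values - basis.mean_curve) @ basis.components.T


def pca_scores_matrix(values: np.ndarray, basis: PcaBasis) -> np.ndarray:
    """Batch form of :func:`pca_scores` for rows of ``values``."""
    V = np.asarray(values, dtype=float)
    if V.shape[1] != basis.n_frames:
        raise ValueError(f"curve length {V.shape[1]} != basis length {basis.n_frames}")
    return (V - basis.mean_curve) @ basis.components.T


def feature_vector(tic, basis: PcaBasis, n_pre: int) -> FeatureVector:
    """The full 7-feature description of one curve (kinetic block then PCA)."""
    kin = kinetic_features(tic, n_pre)
    scores = pca_scores(tic, basis)
    return FeatureVector(kinetic=kin.as_array(), pca=np.asarray(scores, dtype=float))
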