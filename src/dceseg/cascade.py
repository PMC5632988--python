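"""The three-stage cascaded SVM voxel classifier.

Three binary RBF-kernel SVMs are trained one-vs-rest on the full training
table, each with the feature subset that best separates its target class:

1. vessel vs rest — the 5 kinetic features;
2. cavity vs rest — the 2 PCA features;
3. normal vs rest — the 5 kinetic features.

At test time every voxel in a rough search ROI is normalized, featurized
with the frozen PCA basis and training standardization, and run through the
stages in order: voxels labeled vessel are removed first, then cavity, then
normal tissue; the residual voxels are the tumor segmentation.  The three
stage masks plus the tumor mask always partition the ROI exactly.

(C, gamma) for each stage are chosen by stratified k-fold cross-validation
over powers-of-two grids, maximizing CV accuracy with ties broken toward the
smallest C then the smallest gamma (prefer the smoothest model).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset import RoiRect, TissueClass, TrainingTable, standardize
from .features import (
    KINETIC_INDICES,
    PCA_INDICES,
    PcaBasis,
    kinetic_features_matrix,
    pca_scores_matrix,
)
from .tic import DEFAULT_CLAMP_EPS, DEFAULT_N_PRE, DynamicSeries, normalize_tics

__all__ = [
    "StageSpec",
    "SvmConfig",
    "TrainedStage",
    "CascadeModel",
    "SegmentationResult",
    "DEFAULT_STAGES",
    "train_stage",
    "train_cascade",
    "segment",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class StageSpec:
    """One stage of the cascade: which class it removes, with which features,
    at which position in the sequence."""

    target_class: TissueClass
    feature_indices: tuple[int, ...]
    order_index: int


#: The fixed stage plan: vessels first, then cavity, then normal tissue.
DEFAULT_STAGES = (
    StageSpec(TissueClass.VESSEL, KINETIC_INDICES, 1),
    StageSpec(TissueClass.CAVITY, PCA_INDICES, 2),
    StageSpec(TissueClass.NORMAL, KINETIC_INDICES, 3),
)


def _pow2(lo: int, hi: int, step: int = 2) -> tuple[float, ...]:
    return tuple(float(2.0**e) for e in range(lo, hi + 1, step))


@dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM hyperparameter search settings.

    The grids are the canonical powers-of-two ranges C in 2^-5..2^15 and
    gamma in 2^-15..2^3, searched with stratified ``cv_folds``-fold CV.
    """

    c_grid: tuple[float, ...] = _pow2(-5, 15)
    gamma_grid: tuple[float, ...] = _pow2(-15, 3)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be nonempty")


@dataclass
class TrainedStage:
    spec: StageSpec
    classifier: SVC
    C: float
    gamma: float
    cv_accuracy: float


@dataclass
class CascadeModel:
    """Everything needed to segment new series: the frozen PCA basis, the
    training standardization statistics, and the three ordered stages."""

    basis: PcaBasis
    feature_means: np.ndarray
    feature_sds: np.ndarray
    stages: list[TrainedStage]
    n_pre: int = DEFAULT_N_PRE
    clamp_eps: float = DEFAULT_CLAMP_EPS

    def __post_init__(self) -> None:
        if [s.spec.order_index for s in self.stages] != sorted(
            s.spec.order_index for s in self.stages
        ):
            raise ValueError("stages must be stored in order")


def _cv_folds(y: np.ndarray, cv_folds: int, seed: int):
    """Stratified folds, degrading to leave-one-out for tiny tables."""
    counts = np.bincount(y, minlength=2)
    n_splits = min(cv_folds, int(counts.min()))
    if n_splits >= 2:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        return list(skf.split(np.zeros_like(y), y))
    n = len(y)
    idx = np.arange(n)
    return [(np.delete(idx, i), np.array([i])) for i in range(n)]


def _cv_accuracy(X: np.ndarray, y: np.ndarray, folds, C: float, gamma: float) -> float:
    correct = 0
    total = 0
    for tr, te in folds:
        ytr = y[tr]
        if ytr.min() == ytr.max():  # single-class fold: predict the majority
            pred = np.full(len(te), ytr[0])
        else:
            clf = SVC(C=C, gamma=gamma, kernel="rbf")
            clf.fit(X[tr], ytr)
            pred = clf.predict(X[te])
        correct += int((pred == y[te]).sum())
        total += len(te)
    return correct / total


def train_stage(
    table: TrainingTable, spec: StageSpec, config: SvmConfig = SvmConfig()
) -> TrainedStage:
    """Train one one-vs-rest stage with grid-searched (C, gamma).

    Ties in CV accuracy are broken toward the smallest C then the smallest
    gamma, so training is fully deterministic for a fixed seed.
    """
    y = np.array([lab == spec.target_class for lab in table.labels], dtype=int)
    if y.sum() == 0:
        raise ValueError(f"training table has no {spec.target_class.value} rows")
    if y.sum() == len(y):
        raise ValueError("training table has no non-target rows")
    X = table.features[:, list(spec.feature_indices)]
    folds = _cv_folds(y, config.cv_folds, config.seed)

    best = None
    for C in config.c_grid:
        for gamma in config.gamma_grid:
            acc = _cv_accuracy(X, y, folds, C, gamma)
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, gamma)
    cv_acc, C, gamma = best
    clf = SVC(C=C, gamma=gamma, kernel="rbf")
    clf.fit(X, y)
    return TrainedStage(spec=spec, classifier=clf, C=C, gamma=gamma, cv_accuracy=cv_acc)


def train_cascade(
    table: TrainingTable,
    basis: PcaBasis,
    config: SvmConfig = SvmConfig(),
    stages: tuple[StageSpec, ...] = DEFAULT_STAGES,
    n_pre: int = DEFAULT_N_PRE,
    clamp_eps: float = DEFAULT_CLAMP_EPS,
) -> CascadeModel:
    """Train all three stages on the full table and package the model."""
    present = set(table.labels)
    for cls in TissueClass:
        if cls not in present:
            raise ValueError(f"training table is missing class {cls.value}")
    trained = [train_stage(table, spec, config) for spec in stages]
    return CascadeModel(
        basis=basis,
        feature_means=table.feature_means,
        feature_sds=table.feature_sds,
        stages=trained,
        n_pre=n_pre,
        clamp_eps=clamp_eps,
    )


@dataclass
class SegmentationResult:
    """Tumor mask plus the per-stage removal masks; together they partition
    the search ROI exactly."""

    tumor_mask: np.ndarray
    stage_masks: dict
    roi: RoiRect


def segment(
    series: DynamicSeries, test_roi: RoiRect, model: CascadeModel
) -> SegmentationResult:
    """Voxel-by-voxel cascade segmentation of a search ROI.

    Every ROI voxel's curve is normalized and featurized with the model's
    frozen basis and standardization; the stages then remove vessel, cavity
    and normal voxels in order.  The residual voxels form the tumor mask.
    """
    test_roi.validate(series.spatial_shape)
    raw = test_roi.voxel_block(series)
    if raw.shape[0] == 0:
        raise ValueError("empty test ROI")

    values, _, _ = normalize_tics(raw, n_pre=model.n_pre, clamp_eps=model.clamp_eps)
    K, _ = kinetic_features_matrix(values, model.n_pre)
    P = pca_scores_matrix(values, model.basis)
    F = standardize(np.hstack([K, P]), model.feature_means, model.feature_sds)

    w = test_roi.y1 - test_roi.y0
    remaining = np.arange(F.shape[0])
    removed_at: dict[TissueClass, np.ndarray] = {}
    for stage in model.stages:
        if remaining.size:
            pred = stage.classifier.predict(
                F[remaining][:, list(stage.spec.feature_indices)]
            )
        else:
            pred = np.empty(0, dtype=int)
        removed_at[stage.spec.target_class] = remaining[pred == 1]
        remaining = remaining[pred == 0]

    def to_mask(flat_idx: np.ndarray) -> np.ndarray:
        mask = np.zeros(series.spatial_shape, dtype=bool)
        xs = test_roi.x0 + flat_idx // w
        ys = test_roi.y0 + flat_idx % w
        mask[xs, ys, test_roi.slice_index] = True
        return mask

    return SegmentationResult(
        tumor_mask=to_mask(remaining),
        stage_masks={cls: to_mask(idx) for cls, idx in removed_at.items()},
        roi=test_roi,
    )


# --- persistence ------------------------------------------------------------

_MODEL_JSON = "model.json"


def save_model(model: CascadeModel, path) -> None:
    """Persist a model to a directory: JSON metadata + one classifier file
    per stage.  ``load_model`` reproduces identical segmentations."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_pre": model.n_pre,
        "clamp_eps": model.clamp_eps,
        "feature_means": model.feature_means.tolist(),
        "feature_sds": model.feature_sds.tolist(),
        "basis": {
            "mean_curve": model.basis.mean_curve.tolist(),
            "components": model.basis.components.tolist(),
            "eigenvalues": model.basis.eigenvalues.tolist(),
        },
        "stages": [
            {
                "target_class": s.spec.target_class.value,
                "feature_indices": list(s.spec.feature_indices),
                "order_index": s.spec.order_index,
                "C": s.C,
                "gamma": s.gamma,
                "cv_accuracy": s.cv_accuracy,
                "file": f"stage_{s.spec.order_index}.joblib",
            }
            for s in model.stages
        ],
    }
    (path / _MODEL_JSON).write_text(json.dumps(meta, indent=2, sort_keys=True))
    for s in model.stages:
        joblib.dump(s.classifier, path / f"stage_{s.spec.order_index}.joblib")


def load_model(path) -> CascadeModel:
    path = Path(path)
    meta = json.loads((path / _MODEL_JSON).read_text())
    stages = []
    for s in sorted(meta["stages"], key=lambda d: d["order_index"]):
        spec = StageSpec(
            target_class=TissueClass(s["target_class"]),
            feature_indices=tuple(s["feature_indices"]),
            order_index=s["order_index"],
        )
        stages.append(
            TrainedStage(
                spec=spec,
                classifier=joblib.load(path / s["file"]),
                C=s["C"],
                gamma=s["gamma"],
                cv_accuracy=s["cv_accuracy"],
            )
        )
    basis = PcaBasis(
        mean_curve=np.array(meta["basis"]["mean_curve"]),
        components=np.array(meta["basis"]["components"]),
        eigenvalues=np.array(meta["basis"]["eigenvalues"]),
    )
    return CascadeModel(
        basis=basis,
        feature_means=np.array(meta["feature_means"]),
        feature_sds=np.array(meta["feature_sds"]),
        stages=stages,
        n_pre=meta["n_pre"],
        clamp_eps=meta["clamp_eps"],
    )
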