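"""Stage training, grid search, sequential segmentation, persistence."""

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from dceseg import (
    CLASS_ORDER,
    DEFAULT_STAGES,
    SvmConfig,
    TissueClass,
    load_model,
    save_model,
    segment,
    train_cascade,
    train_stage,
)
from dceseg.dataset import TrainingTable
from dceseg.features import FEATURE_NAMES


def table_from(features, labels):
    X = np.asarray(features, dtype=float)
    means, sds = X.mean(axis=0), X.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)
    return TrainingTable(
        features=(X - means) / sds,
        labels=list(labels),
        feature_means=means,
        feature_sds=sds,
        raw_features=X,
    )


def separated_table(rng, n_per_class=20, sep=6.0):
    """Four Gaussian blobs in 7D, separated within both the kinetic block
    (columns 0-4) and the PCA block (columns 5-6) so every stage's feature
    subset can distinguish its target class."""
    rows, labels = [], []
    for i, cls in enumerate(CLASS_ORDER):
        center = np.zeros(7)
        center[i % 5] = sep * (i + 1)  # kinetic block
        center[5] = sep * i            # PCA block
        center[6] = -sep * i
        rows.append(center + rng.normal(0, 0.3, size=(n_per_class, 7)))
        labels += [cls] * n_per_class
    return table_from(np.vstack(rows), labels)


class TestTrainStage:
    def test_separable_data_reaches_perfect_cv(self, rng):
        table = separated_table(rng)
        stage = train_stage(table, DEFAULT_STAGES[0])
        assert stage.cv_accuracy == 1.0
        # cross-check separability with an independent classifier
        y = [l == TissueClass.VESSEL for l in table.labels]
        knn = KNeighborsClassifier(3).fit(table.features[:, :5], y)
        assert knn.score(table.features[:, :5], y) == 1.0
        pred = stage.classifier.predict(table.features[:, :5])
        assert np.array_equal(pred, np.array(y, dtype=int))

    def test_ambiguous_duplicate_rows_cap_cv_below_one(self, rng):
        table = separated_table(rng, n_per_class=10)
        # duplicate a normal-class row exactly into the vessel class
        feats = table.features.copy()
        vessel_rows = [i for i, l in enumerate(table.labels) if l == TissueClass.VESSEL]
        normal_rows = [i for i, l in enumerate(table.labels) if l == TissueClass.NORMAL]
        feats[vessel_rows] = feats[normal_rows[: len(vessel_rows)]]
        tab = TrainingTable(
            features=feats,
            labels=table.labels,
            feature_means=table.feature_means,
            feature_sds=table.feature_sds,
        )
        stage = train_stage(tab, DEFAULT_STAGES[0])
        assert stage.cv_accuracy < 1.0

    def test_deterministic_choice(self, rng):
        table = separated_table(rng)
        a = train_stage(table, DEFAULT_STAGES[2], SvmConfig(seed=3))
        b = train_stage(table, DEFAULT_STAGES[2], SvmConfig(seed=3))
        assert (a.C, a.gamma, a.cv_accuracy) == (b.C, b.gamma, b.cv_accuracy)

    def test_chosen_pair_belongs_to_grids(self, rng):
        config = SvmConfig()
        stage = train_stage(separated_table(rng), DEFAULT_STAGES[1], config)
        assert stage.C in config.c_grid
        assert stage.gamma in config.gamma_grid

    def test_missing_target_class_rejected(self, rng):
        table = separated_table(rng)
        table.labels = [
            TissueClass.TUMOR if l == TissueClass.VESSEL else l for l in table.labels
        ]
        with pytest.raises(ValueError, match="vessel"):
            train_stage(table, DEFAULT_STAGES[0])


class TestTrainCascade:
    def test_well_separated_table_trains_accurately(self, rng):
        model = train_cascade(separated_table(rng), basis=_dummy_basis())
        for stage in model.stages:
            assert stage.cv_accuracy >= 0.95

    def test_four_row_table_runs_leave_one_out(self, rng):
        table = separated_table(rng, n_per_class=1)
        model = train_cascade(table, basis=_dummy_basis())
        assert len(model.stages) == 3

    def test_stage_plan_matches_method(self, rng):
        model = train_cascade(separated_table(rng), basis=_dummy_basis())
        plan = [(s.spec.target_class, s.spec.feature_indices) for s in model.stages]
        assert plan == [
            (TissueClass.VESSEL, (0, 1, 2, 3, 4)),
            (TissueClass.CAVITY, (5, 6)),
            (TissueClass.NORMAL, (0, 1, 2, 3, 4)),
        ]

    def test_same_seed_identical_metadata(self, rng):
        table = separated_table(rng)
        a = train_cascade(table, _dummy_basis(), SvmConfig(seed=1))
        b = train_cascade(table, _dummy_basis(), SvmConfig(seed=1))
        meta = lambda m: [(s.C, s.gamma, s.cv_accuracy) for s in m.stages]
        assert meta(a) == meta(b)


def _dummy_basis():
    from dceseg.features import PcaBasis

    comps = np.zeros((2, 65))
    comps[0, 0] = comps[1, 1] = 1.0
    return PcaBasis(mean_curve=np.zeros(65), components=comps, eigenvalues=np.array([1.0, 0.5]))


class TestSegment:
    def test_masks_partition_roi(self, noiseless_setup):
        sample = noiseless_setup["test"][0]
        seg = segment(sample.series, sample.test_roi, noiseless_setup["model"])
        roi = sample.test_roi
        union = seg.tumor_mask.copy()
        total = int(seg.tumor_mask.sum())
        for mask in seg.stage_masks.values():
            assert not (union & mask).any()  # pairwise disjoint
            union |= mask
            total += int(mask.sum())
        in_roi = np.zeros_like(union)
        in_roi[roi.x0 : roi.x1, roi.y0 : roi.y1, roi.slice_index] = True
        assert np.array_equal(union, in_roi)
        assert total == roi.n_voxels

    def test_noiseless_recovery_is_exact(self, noiseless_setup):
        for sample in noiseless_setup["test"]:
            seg = segment(sample.series, sample.test_roi, noiseless_setup["model"])
            assert np.array_equal(seg.tumor_mask, sample.tumor_mask)

    def test_vessel_only_roi_yields_empty_tumor_mask(self, noiseless_setup):
        sample = noiseless_setup["test"][0]
        vessel_roi = next(
            r for r in sample.train_rois if r.label == TissueClass.VESSEL
        )
        seg = segment(sample.series, vessel_roi, noiseless_setup["model"])
        assert not seg.tumor_mask.any()
        assert seg.stage_masks[TissueClass.VESSEL].sum() == vessel_roi.n_voxels


class TestPersistence:
    def test_round_trip_reproduces_segmentation(self, noiseless_setup, tmp_path):
        model = noiseless_setup["model"]
        save_model(model, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        assert [(s.C, s.gamma) for s in loaded.stages] == [
            (s.C, s.gamma) for s in model.stages
        ]
        sample = noiseless_setup["test"][0]
        a = segment(sample.series, sample.test_roi, model)
        b = segment(sample.series, sample.test_roi, loaded)
        assert np.array_equal(a.tumor_mask, b.tumor_mask)
        for cls in a.stage_masks:
            assert np.array_equal(a.stage_masks[cls], b.stage_masks[cls])
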