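"""Kinetic curve parameters, PCA basis fitting, and the 7-feature vector."""

import numpy as np
import pytest
from sklearn.decomposition import PCA as SkPCA

from dceseg import (
    FEATURE_NAMES,
    feature_vector,
    fit_pca,
    kinetic_features,
    normalize_tic,
    pca_scores,
)
from dceseg.features import kinetic_features_matrix


def kinetic_oracle(values, n_pre):
    """Literal scalar transcription of the five curve-parameter definitions."""
    T = len(values)
    i_max = max(values)
    t_peak = 1 + list(values).index(i_max)
    t_10 = None
    if i_max > 0:
        for t in range(n_pre + 1, T + 1):
            if values[t - 1] >= 0.10 * i_max:
                t_10 = t
                break
    if t_10 is None:
        t_10 = t_peak
    t_onset = t_10 - n_pre
    wash_in = 0.0
    if i_max > 0 and t_peak != t_10:
        wash_in = (values[t_peak - 1] - values[t_10 - 1]) / (t_peak - t_10)
    wash_out = 0.0
    if t_peak != T:
        wash_out = (values[t_peak - 1] - values[T - 1]) / (T - t_peak)
    return i_max, t_peak, t_onset, wash_in, wash_out


class TestKineticFeatures:
    def test_step_curve(self):
        values = np.concatenate([np.zeros(8), np.ones(57)])
        k = kinetic_features(values, n_pre=8)
        assert k.i_max == 1.0
        assert k.t_peak == 9
        assert k.t_10pct == 9
        assert k.t_onset == 1
        assert k.wash_in == 0.0  # degenerate: t_peak == t_10pct
        assert k.wash_out == 0.0  # flat tail

    def test_constant_zero_curve(self):
        k = kinetic_features(np.zeros(65), n_pre=8)
        assert (k.i_max, k.t_peak, k.wash_in, k.wash_out) == (0.0, 1, 0.0, 0.0)

    def test_piecewise_linear_ramp_matches_oracle(self):
        # ramp up frames 9-28 to 2.0, ramp down frames 29-65 to 0.8
        t = np.arange(1, 66)
        values = np.where(t <= 8, 0.0, np.where(t <= 28, 2.0 * (t - 8) / 20, 2.0 - 1.2 * (t - 28) / 37))
        k = kinetic_features(values, n_pre=8)
        o = kinetic_oracle(values, 8)
        assert (k.i_max, k.t_peak, k.t_onset) == (o[0], o[1], o[2])
        assert k.wash_in == pytest.approx(o[3], rel=1e-12)
        assert k.wash_out == pytest.approx(o[4], rel=1e-12)

    def test_random_curves_match_oracle(self, rng):
        V = rng.normal(0.5, 1.0, size=(200, 65))
        K, _ = kinetic_features_matrix(V, 8)
        for i in range(200):
            o = kinetic_oracle(V[i], 8)
            np.testing.assert_allclose(K[i], o, rtol=1e-9, atol=1e-12)

    def test_tie_at_maximum_takes_first_frame(self):
        values = np.zeros(65)
        values[20] = values[40] = 1.0
        assert kinetic_features(values, n_pre=8).t_peak == 21

    def test_nonfinite_rejected(self):
        values = np.zeros(65)
        values[10] = np.nan
        with pytest.raises(ValueError, match="finite"):
            kinetic_features(values, n_pre=8)

    def test_monotone_curves_have_nonnegative_rates(self, rng):
        """Nondecreasing rise to the peak implies wash_in >= 0; nonincreasing
        decay after it implies wash_out >= 0."""
        for _ in range(20):
            peak = int(rng.integers(12, 60))
            up = np.sort(rng.uniform(0, 2, peak))
            down = -np.sort(-rng.uniform(0, up[-1], 65 - peak))
            k = kinetic_features(np.concatenate([up, down]), n_pre=8)
            assert k.wash_in >= 0
            assert k.wash_out >= 0


class TestPca:
    def test_rank_one_data(self, rng):
        base = rng.normal(size=65)
        v = rng.normal(size=65)
        v /= np.linalg.norm(v)
        curves = [base + a * v for a in (-3.0, -1.0, 0.5, 1.0, 2.5)]
        basis = fit_pca(curves)
        # component 1 is ±v; the sign rule makes the comparison deterministic
        c = v if v[np.argmax(np.abs(v))] > 0 else -v
        np.testing.assert_allclose(basis.components[0], c, atol=1e-8)
        assert basis.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_constructed_variance_ratio(self, rng):
        u = np.zeros(65)
        u[0] = 1.0
        w = np.zeros(65)
        w[1] = 1.0
        # symmetric spreads with variances 4 and 1 along orthogonal directions
        curves = [a * u + b * w for a in (-2.0, 2.0) for b in (-1.0, 1.0)]
        basis = fit_pca(curves)
        assert basis.eigenvalues[0] / basis.eigenvalues[1] == pytest.approx(4.0)

    def test_matches_sklearn_eigendecomposition(self, rng):
        curves = rng.normal(size=(30, 65))
        basis = fit_pca(curves)
        ref = SkPCA(n_components=2).fit(curves)
        for mine, theirs, lam, lam_ref in zip(
            basis.components, ref.components_, basis.eigenvalues, ref.explained_variance_
        ):
            theirs = theirs if theirs[np.argmax(np.abs(theirs))] > 0 else -theirs
            np.testing.assert_allclose(mine, theirs, atol=1e-8)
            assert lam == pytest.approx(lam_ref, rel=1e-8)

    def test_orthonormality_and_order(self, rng):
        basis = fit_pca(rng.normal(size=(20, 65)))
        gram = basis.components @ basis.components.T
        np.testing.assert_allclose(gram, np.eye(2), atol=1e-8)
        assert basis.eigenvalues[0] >= basis.eigenvalues[1] >= 0

    def test_too_few_curves_rejected(self, rng):
        with pytest.raises(ValueError, match="3"):
            fit_pca(rng.normal(size=(2, 65)))

    def test_two_component_reconstruction_not_worse_than_one(self, rng):
        """Captured variance is monotone in the number of components."""
        curves = rng.normal(size=(40, 65))
        basis = fit_pca(curves)
        X = curves - basis.mean_curve
        s = X @ basis.components.T
        err1 = np.linalg.norm(X - np.outer(s[:, 0], basis.components[0]))
        err2 = np.linalg.norm(X - s @ basis.components)
        assert err2 <= err1 + 1e-12


class TestPcaScores:
    def test_mean_curve_scores_zero(self, rng):
        basis = fit_pca(rng.normal(size=(10, 65)))
        np.testing.assert_allclose(pca_scores(basis.mean_curve, basis), 0.0, atol=1e-12)

    def test_component_direction_recovers_coefficient(self, rng):
        basis = fit_pca(rng.normal(size=(10, 65)))
        tic = basis.mean_curve + 3.0 * basis.components[0]
        np.testing.assert_allclose(pca_scores(tic, basis), [3.0, 0.0], atol=1e-8)

    def test_matches_explicit_dot_products(self, rng):
        basis = fit_pca(rng.normal(size=(10, 65)))
        tic = rng.normal(size=65)
        expected = [float(np.dot(tic - basis.mean_curve, c)) for c in basis.components]
        np.testing.assert_allclose(pca_scores(tic, basis), expected, rtol=1e-12)

    def test_length_mismatch_rejected(self, rng):
        basis = fit_pca(rng.normal(size=(10, 65)))
        with pytest.raises(ValueError, match="length"):
            pca_scores(np.zeros(64), basis)


class TestFeatureVector:
    def test_length_is_seven(self, rng):
        basis = fit_pca(rng.normal(size=(10, 65)))
        fv = feature_vector(rng.normal(size=65), basis, n_pre=8)
        assert fv.as_7.shape == (7,)
        assert len(FEATURE_NAMES) == 7

    def test_composition(self, rng):
        basis = fit_pca(rng.normal(size=(10, 65)))
        tic = rng.normal(size=65)
        fv = feature_vector(tic, basis, n_pre=8)
        np.testing.assert_array_equal(fv.kinetic, kinetic_features(tic, 8).as_array())
        np.testing.assert_array_equal(fv.pca, pca_scores(tic, basis))

    def test_features_invariant_to_raw_intensity_scale(self, rng):
        basis = fit_pca(rng.normal(size=(10, 65)))
        raw = rng.uniform(50, 200, size=65)
        a = feature_vector(normalize_tic(raw, 8), basis, 8).as_7
        b = feature_vector(normalize_tic(7.3 * raw, 8), basis, 8).as_7
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-9)
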