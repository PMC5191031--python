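"""CSP correctness: covariance contracts, eigen-identities, oracle match."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import linalg

from erders_bmi import (
    apply_csp,
    features_from_epochs,
    fit_csp,
    log_variance_features,
    normalized_covariance,
    trial_covariance,
)
from erders_bmi.csp import DegenerateFeatureError, DegenerateTrialError
from tests.conftest import feature_data


def _two_class_gaussian(rng, n_ch=4, n_trials=30, n_t=500, boost=4.0):
    """Class 1 variance boosted on the first channel, class 2 on the last."""
    x1 = rng.standard_normal((n_trials, n_ch, n_t))
    x2 = rng.standard_normal((n_trials, n_ch, n_t))
    x1[:, 0] *= boost
    x2[:, -1] *= boost
    data = np.concatenate([x1, x2])
    labels = np.array(["a"] * n_trials + ["b"] * n_trials)
    return data, labels


class TestNormalizedCovariance:
    def test_trace_is_one(self, rng):
        w = normalized_covariance(rng.standard_normal((5, 400)))
        assert np.trace(w) == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(w, w.T)
        assert np.all(linalg.eigvalsh(w) > -1e-12)

    def test_white_trial_near_scaled_identity(self, rng):
        n = 4
        w = normalized_covariance(rng.standard_normal((n, 200_000)))
        assert np.allclose(w, np.eye(n) / n, atol=0.002)

    def test_perfectly_correlated_channels_rank_one(self, rng):
        x = rng.standard_normal(1000)
        w = normalized_covariance(np.vstack([x, x]))
        assert w[0, 1] == pytest.approx(w[0, 0], abs=1e-12)
        assert np.linalg.matrix_rank(w, tol=1e-10) == 1

    def test_zero_trial_raises(self):
        with pytest.raises(DegenerateTrialError):
            normalized_covariance(np.zeros((3, 100)))

    def test_segmented_mode_averages_segment_covariances(self, rng):
        x = rng.standard_normal((3, 1024))
        seg = int(0.2 * 512)
        expected = np.mean(
            [
                normalized_covariance(x[:, k * seg : (k + 1) * seg])
                for k in range(1024 // seg)
            ],
            axis=0,
        )
        assert np.allclose(trial_covariance(x, fs=512.0), expected)


class TestFitCsp:
    def test_eigenvalue_pairs_sum_to_one(self, small_epochs):
        data, labels = feature_data(small_epochs)
        model = fit_csp(data, labels, ("left_hand", "both_feet"), m=2, fs=512.0)
        assert np.abs(model.eigvals_class1 + model.eigvals_class2 - 1.0).max() < 1e-8

    def test_projected_class_covariances_diagonal(self, rng):
        data, labels = _two_class_gaussian(rng)
        model = fit_csp(data, labels, ("a", "b"), m=1, covariance_mode="whole")
        for cls in ("a", "b"):
            wbar = np.mean(
                [normalized_covariance(t) for t in data[labels == cls]], axis=0
            )
            proj = model.full_projection @ wbar @ model.full_projection.T
            off = proj - np.diag(np.diag(proj))
            assert np.abs(off).max() < 1e-6

    def test_whitening_identity(self, rng):
        """Filters diagonalize the composite covariance to the identity."""
        data, labels = _two_class_gaussian(rng)
        w1 = np.mean([normalized_covariance(t) for t in data[labels == "a"]], axis=0)
        w2 = np.mean([normalized_covariance(t) for t in data[labels == "b"]], axis=0)
        model = fit_csp(data, labels, ("a", "b"), m=1, covariance_mode="whole")
        b = model.full_projection
        assert np.allclose(b @ (w1 + w2) @ b.T, np.eye(4), atol=1e-8)

    def test_identical_distributions_give_half_eigenvalues(self, rng):
        x = rng.standard_normal((40, 3, 2000))
        labels = np.array(["a", "b"] * 20)
        model = fit_csp(x, labels, ("a", "b"), m=1, covariance_mode="whole")
        assert np.abs(model.eigvals_class1 - 0.5).max() < 0.05

    def test_axis_aligned_toy_recovers_coordinate_filters(self, rng):
        x1 = rng.standard_normal((50, 2, 4000))
        x2 = rng.standard_normal((50, 2, 4000))
        x1[:, 0] *= 5.0
        x2[:, 1] *= 5.0
        data = np.concatenate([x1, x2])
        labels = np.array(["a"] * 50 + ["b"] * 50)
        model = fit_csp(data, labels, ("a", "b"), m=1, covariance_mode="whole")
        for row, axis in ((model.projection[0], 0), (model.projection[1], 1)):
            cos = abs(row[axis]) / np.linalg.norm(row)
            assert cos > 0.99

    @pytest.mark.parametrize("n_ch", [2, 4, 6])
    def test_matches_generalized_eigendecomposition_oracle(self, rng, n_ch):
        """Filters equal eigenvectors of W1 v = λ (W1+W2) v up to sign/scale."""
        data, labels = _two_class_gaussian(rng, n_ch=n_ch)
        w1 = np.mean([normalized_covariance(t) for t in data[labels == "a"]], axis=0)
        w2 = np.mean([normalized_covariance(t) for t in data[labels == "b"]], axis=0)
        evals, evecs = linalg.eigh(w1, w1 + w2)  # ascending
        model = fit_csp(data, labels, ("a", "b"), m=1, covariance_mode="whole")
        assert np.allclose(model.eigvals_class1, evals[::-1], atol=1e-8)
        for j in range(n_ch):
            v_oracle = evecs[:, ::-1][:, j]
            v_model = model.full_projection[j]
            cos = abs(v_oracle @ v_model) / (
                np.linalg.norm(v_oracle) * np.linalg.norm(v_model)
            )
            assert cos > 1.0 - 1e-8

    def test_fit_is_bit_reproducible(self, rng):
        data, labels = _two_class_gaussian(rng)
        m1 = fit_csp(data, labels, ("a", "b"), m=2)
        m2 = fit_csp(data, labels, ("a", "b"), m=2)
        assert np.array_equal(m1.full_projection, m2.full_projection)

    def test_m_too_large_rejected(self, rng):
        data, labels = _two_class_gaussian(rng, n_ch=4)
        with pytest.raises(ValueError):
            fit_csp(data, labels, ("a", "b"), m=3)

    def test_too_few_trials_rejected(self, rng):
        data = rng.standard_normal((3, 4, 100))
        labels = np.array(["a", "a", "b"])
        with pytest.raises(ValueError):
            fit_csp(data, labels, ("a", "b"), m=1)

    def test_json_round_trip(self, small_epochs, tmp_path):
        from erders_bmi import CSPModel

        data, labels = feature_data(small_epochs)
        model = fit_csp(
            data, labels, ("left_hand", "both_feet"), m=2, fs=512.0,
            channel_labels=small_epochs.channel_labels,
        )
        path = tmp_path / "csp.json"
        model.to_json(path)
        back = CSPModel.from_json(path)
        assert np.array_equal(back.projection, model.projection)
        assert back.channel_labels == model.channel_labels


class TestApplyAndFeatures:
    def test_projection_is_linear(self, rng):
        data, labels = _two_class_gaussian(rng)
        model = fit_csp(data, labels, ("a", "b"), m=2)
        v1, v2 = data[0], data[1]
        out = apply_csp(model, 2.0 * v1 - 0.5 * v2)
        assert np.allclose(out, 2.0 * apply_csp(model, v1) - 0.5 * apply_csp(model, v2))

    def test_zero_trial_maps_to_zero(self, rng):
        data, labels = _two_class_gaussian(rng)
        model = fit_csp(data, labels, ("a", "b"), m=2)
        assert np.all(apply_csp(model, np.zeros_like(data[0])) == 0)

    def test_channel_count_mismatch_raises(self, rng):
        data, labels = _two_class_gaussian(rng)
        model = fit_csp(data, labels, ("a", "b"), m=2)
        with pytest.raises(ValueError):
            apply_csp(model, np.zeros((3, 100)))

    def test_equal_row_variances_give_log_half(self, rng):
        z = np.vstack([rng.standard_normal(100_000)] * 2)
        z[1] = rng.standard_normal(100_000)
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        f = log_variance_features(z)
        assert np.allclose(f, np.log(0.5), atol=1e-6)

    def test_known_variance_ratio(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(200_000)
        z = np.vstack([a * np.sqrt(3.0), rng.standard_normal(200_000)])
        f = log_variance_features(z)
        assert f[0] == pytest.approx(np.log(0.75), abs=0.01)
        assert f[1] == pytest.approx(np.log(0.25), abs=0.01)

    def test_features_scale_invariant(self, rng):
        z = rng.standard_normal((4, 1000))
        assert np.allclose(
            log_variance_features(z), log_variance_features(z * 17.3), atol=1e-12
        )

    def test_features_exp_sums_to_one(self, rng):
        z = rng.standard_normal((4, 1000)) * np.array([[1.0], [2.0], [0.5], [3.0]])
        f = log_variance_features(z)
        assert np.exp(f).sum() == pytest.approx(1.0, abs=1e-8)

    def test_zero_variance_row_raises(self, rng):
        z = rng.standard_normal((2, 100))
        z[1] = 0.0
        with pytest.raises(DegenerateFeatureError):
            log_variance_features(z)

    def test_feature_separability_on_synthetic_classes(self, small_epochs):
        """First/last CSP features separate the classes by >> standard error."""
        data, labels = feature_data(small_epochs)
        model = fit_csp(
            data, labels, ("left_hand", "both_feet"), m=2, fs=512.0,
            channel_labels=small_epochs.channel_labels,
        )
        feats = features_from_epochs(model, data)
        left = feats[labels == "left_hand"]
        feet = feats[labels == "both_feet"]
        for j in (0, 2 * model.m - 1):
            gap = abs(left[:, j].mean() - feet[:, j].mean())
            se = np.sqrt(
                left[:, j].var(ddof=1) / len(left) + feet[:, j].var(ddof=1) / len(feet)
            )
            assert gap > 5.0 * se
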