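"""1-D GMM fitting by EM, discretization, spatial patterns, channel scores."""

import numpy as np
import pytest

from semgrid import (
    ElectrodeLayout,
    discretize,
    fit_gmm,
    modal_pattern,
    select_channels,
    to_spatial_pattern,
)
from semgrid.gmm_pattern import UNOCCUPIED, GmmModel, quantile_init


def two_component_sample(rng, n_per=5000, means=(0.0, 10.0), sd=1.0):
    return np.concatenate([
        rng.normal(means[0], sd, n_per),
        rng.normal(means[1], sd, n_per),
    ])


def equal_model(means=(0.0, 10.0)):
    return GmmModel(
        weights=np.full(len(means), 1.0 / len(means)),
        means=np.asarray(means, dtype=float),
        variances=np.ones(len(means)),
        log_likelihood=0.0, n_training=100, converged=True, iterations=1,
        variance_floor=1e-9,
    )


class TestFit:
    def test_degenerate_constant_data(self):
        model = fit_gmm(np.full(50, 7.0), K=1)
        assert model.K == 1
        assert model.means[0] == 7.0
        assert model.weights[0] == 1.0
        assert model.variances[0] == model.variance_floor

    def test_constant_data_with_k_above_one_flagged(self):
        model = fit_gmm(np.full(50, 7.0), K=3)
        assert model.degenerate
        assert model.K == 1

    def test_two_component_recovery(self):
        rng = np.random.default_rng(42)
        x = two_component_sample(rng)
        model = fit_gmm(x, K=2, seed=0)
        assert np.all(np.abs(model.means - np.array([0.0, 10.0])) < 0.1)
        assert np.all(np.abs(model.weights - 0.5) < 0.05)
        assert model.converged

    def test_loglikelihood_monotone(self):
        rng = np.random.default_rng(3)
        x = np.abs(rng.normal(5, 3, 2000))
        model = fit_gmm(x, K=4, seed=1)
        ll = model.ll_history
        slack = 1e-8 * np.maximum(np.abs(ll[:-1]), 1.0)
        assert np.all(np.diff(ll) >= -slack)

    def test_means_amplitude_ordered(self):
        rng = np.random.default_rng(8)
        model = fit_gmm(two_component_sample(rng, means=(12.0, 2.0)), K=2, seed=0)
        assert np.all(np.diff(model.means) > 0)

    def test_matches_reference_em_from_same_start(self):
        """Final log-likelihood agrees with scikit-learn's EM started
        from the identical initialization."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(17)
        x = two_component_sample(rng, n_per=100)
        w0, m0, v0 = quantile_init(x, 3)
        ours = fit_gmm(x, K=3, init=(w0, m0, v0), tol=1e-13, max_iter=2000)
        gm = GaussianMixture(
            n_components=3, covariance_type="full", tol=1e-12, max_iter=2000,
            reg_covar=1e-10, weights_init=w0, means_init=m0.reshape(-1, 1),
            precisions_init=(1.0 / v0).reshape(-1, 1, 1),
        ).fit(x.reshape(-1, 1))
        ref_ll = gm.score(x.reshape(-1, 1)) * len(x)
        assert ours.log_likelihood == pytest.approx(ref_ll, abs=1e-4)

    def test_preconditions(self):
        with pytest.raises(ValueError, match="K must be"):
            fit_gmm(np.ones(100), K=0)
        with pytest.raises(ValueError, match="pooled samples"):
            fit_gmm(np.arange(15.0), K=2)
        with pytest.raises(ValueError, match="distinct"):
            fit_gmm(np.array([0.0, 1.0] * 20), K=3)


class TestDiscretize:
    def test_values_at_means_get_own_index(self):
        model = equal_model((0.0, 5.0, 10.0))
        assert list(discretize(np.array([0.0, 5.0, 10.0]), model)) == [0, 1, 2]

    def test_midpoint_boundary(self):
        model = equal_model((0.0, 10.0))
        assert discretize(np.array([4.9]), model)[0] == 0
        assert discretize(np.array([5.1]), model)[0] == 1

    def test_exact_tie_goes_to_lower_index(self):
        model = equal_model((0.0, 10.0))
        assert discretize(np.array([5.0]), model)[0] == 0

    def test_monotone_assignment_on_grid(self):
        model = equal_model((0.0, 4.0, 10.0))
        grid = np.linspace(-5.0, 15.0, 1000)
        idx = discretize(grid, model)
        assert np.all(np.diff(idx) >= 0)

    def test_pure_function(self):
        rng = np.random.default_rng(0)
        model = equal_model()
        x = rng.normal(5, 3, (40, 4))
        assert np.array_equal(discretize(x, model), discretize(x, model))


class TestSpatialPattern:
    def test_direct_placement(self):
        layout = ElectrodeLayout.grid(2, 2)
        pat = to_spatial_pattern(np.array([0, 1, 2, 3]), layout, K=4)
        assert np.array_equal(pat.grid, [[0, 1], [2, 3]])

    def test_uniform_indices(self):
        layout = ElectrodeLayout.grid(2, 3)
        pat = to_spatial_pattern(np.full(6, 2), layout, K=5)
        assert np.all(pat.grid == 2)

    def test_unoccupied_cells_marked(self):
        layout = ElectrodeLayout(2, 2, [("a", 0, 0), ("b", 1, 1)])
        pat = to_spatial_pattern(np.array([1, 3]), layout, K=4)
        assert pat.grid[0, 1] == UNOCCUPIED
        assert pat.grid[1, 0] == UNOCCUPIED

    def test_round_trip_through_layout(self):
        layout = ElectrodeLayout.grid(4, 4)
        row = np.arange(16) % 5
        pat = to_spatial_pattern(row, layout, K=5)
        assert np.array_equal(pat.flatten(), row)

    def test_errors(self):
        layout = ElectrodeLayout.grid(2, 2)
        with pytest.raises(ValueError, match="length"):
            to_spatial_pattern(np.array([0, 1]), layout, K=2)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            to_spatial_pattern(np.array([0, 1, 2, 0]), layout, K=2)


class TestSelectChannels:
    def test_constant_channel_scores_zero(self):
        rows = np.zeros((40, 2), dtype=int)
        rows[:, 1] = np.arange(40) % 2
        labels = np.array(["a", "b"] * 20)
        scores = dict(select_channels(rows, labels))
        assert scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_aligned_binary_channel_scores_one_bit(self):
        labels = np.array(["a"] * 20 + ["b"] * 20)
        rows = (labels == "b").astype(int)[:, None]
        scores = select_channels(rows, labels)
        assert scores[0][1] == pytest.approx(1.0, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            select_channels(np.zeros((10, 1), dtype=int), np.array(["a"] * 10))


def test_modal_patterns_distinct_across_flexions(flexion_config, flexion_features):
    """Per-class modal spatial patterns are pairwise distinct on the
    strongly separated synthetic flexion data (K=5)."""
    model = fit_gmm(flexion_features, K=5, seed=0)
    rows = discretize(flexion_features, model)
    patterns = {}
    for motion in flexion_config.classes:
        sel = flexion_features.labels == motion
        patterns[motion] = modal_pattern(rows[sel], flexion_config.layout, model.K)
    motions = list(patterns)
    for i, a in enumerate(motions):
        for b in motions[i + 1 :]:
            assert not np.array_equal(patterns[a].grid, patterns[b].grid), (a, b)
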