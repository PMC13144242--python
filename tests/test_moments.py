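"""Stage-1/2 statistics: sample thresholds, polychoric ML, asymptotic weights."""

import numpy as np
import pytest

from catlgm import (
    CategoricalPanel,
    DegenerateCategoryError,
    asymptotic_weights,
    estimate_sample_thresholds,
    polychoric_correlation,
    polychoric_full,
    sample_moments,
)
from catlgm.bvn import rectangle_probabilities
from catlgm.moments import _neg_loglik, contingency_table


def _binary_panel(n0, n1, other=None):
    col = np.repeat([0, 1], [n0, n1])
    other = col if other is None else other
    return CategoricalPanel(data=np.column_stack([col, other]), n_categories=2)


class TestThresholds:
    def test_known_proportions(self):
        panel = _binary_panel(30, 70, np.tile([0, 1], 50))
        tau = estimate_sample_thresholds(panel)
        assert tau[0][0] == pytest.approx(-0.5244, abs=1e-4)
        panel = _binary_panel(50, 50, np.tile([0, 1], 50))
        assert estimate_sample_thresholds(panel)[0][0] == pytest.approx(0.0, abs=1e-12)

    def test_empty_category_raises(self):
        panel = CategoricalPanel(
            data=np.column_stack([np.zeros(100, int), np.tile([0, 1], 50)]),
            n_categories=2,
        )
        with pytest.raises(DegenerateCategoryError):
            estimate_sample_thresholds(panel)


def _bvn_categorical(rho, tx, ty, n, seed):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    y = np.column_stack([z[:, 0], rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]])
    x = np.searchsorted(np.atleast_1d(tx), y[:, 0], side="right")
    w = np.searchsorted(np.atleast_1d(ty), y[:, 1], side="right")
    return x, w


class TestPolychoric:
    def test_independence_gives_zero(self):
        # cell proportions exactly equal to products of margins
        from scipy.special import ndtri

        x = np.repeat([0, 0, 1, 1], [30, 30, 20, 20])
        y = np.array([0, 1] * 50)
        tx, ty = [ndtri(0.6)], [ndtri(0.5)]
        rho = polychoric_correlation(x, y, tx, ty)
        assert rho == pytest.approx(0.0, abs=1e-5)

    def test_tetrachoric_recovery_large_n(self):
        x, y = _bvn_categorical(0.5, [0.0], [0.0], 100_000, 11)
        from scipy.special import ndtri

        tx = [ndtri(np.mean(x == 0))]
        ty = [ndtri(np.mean(y == 0))]
        assert polychoric_correlation(x, y, tx, ty) == pytest.approx(0.5, abs=0.01)

    def test_symmetry(self):
        x, y = _bvn_categorical(-0.4, [-0.83, 0.83], [-0.5, 0.7], 2_000, 5)
        from scipy.special import ndtri

        tx = ndtri(np.cumsum(np.bincount(x, minlength=3))[:-1] / x.size)
        ty = ndtri(np.cumsum(np.bincount(y, minlength=3))[:-1] / y.size)
        assert polychoric_correlation(x, y, tx, ty) == pytest.approx(
            polychoric_correlation(y, x, ty, tx), abs=1e-10
        )

    @pytest.mark.parametrize(
        "rho, tx, ty, seed",
        [
            (0.5, [0.0], [0.0], 1),
            (-0.35, [0.4], [-0.6], 2),
            (0.7, [-0.83, 0.83], [-0.83, 0.83], 3),
            (0.15, [-1.0, 0.5], [-0.3, 1.1], 4),
        ],
    )
    def test_agrees_with_grid_search(self, rho, tx, ty, seed):
        # brute-force likelihood scan is the oracle for the scalar MLE
        x, y = _bvn_categorical(rho, tx, ty, 500, seed)
        table = contingency_table(x, y, len(tx) + 1, len(ty) + 1)
        grid = np.arange(-0.9999, 0.9999, 1e-4)
        vals = [_neg_loglik(r, table, np.asarray(tx), np.asarray(ty)) for r in grid]
        oracle = grid[int(np.argmin(vals))]
        est = polychoric_correlation(x, y, tx, ty)
        assert est == pytest.approx(oracle, abs=1e-3)

    def test_perfect_association_flags_boundary(self):
        x = np.repeat([0, 1], 50)
        res = polychoric_full(x, x, [0.0], [0.0])
        assert res.boundary


class TestWeights:
    def test_binary_threshold_variance_delta_method(self):
        # tau at 0: Var = p(1-p) / (n phi(0)^2) = 1.5708 / n
        n = 400
        panel = _binary_panel(n // 2, n // 2, np.tile([0, 1], n // 2))
        tau = estimate_sample_thresholds(panel)
        corr = np.array([[1.0, 0.2], [0.2, 1.0]])
        w = asymptotic_weights(panel, tau, corr)
        assert w[0] == pytest.approx(np.pi / 2 / n, rel=1e-6)

    def test_one_over_n_scaling(self):
        x, y = _bvn_categorical(0.45, [0.0], [0.0], 4_000, 21)
        half = CategoricalPanel(np.column_stack([x, y])[:2_000], n_categories=2)
        full = CategoricalPanel(np.column_stack([x, y]), n_categories=2)
        wh = asymptotic_weights(half, estimate_sample_thresholds(half),
                                sample_moments(half).correlations)
        wf = asymptotic_weights(full, estimate_sample_thresholds(full),
                                sample_moments(full).correlations)
        ratio = wh / wf
        assert np.all(ratio > 1.4) and np.all(ratio < 2.8)

    def test_all_positive_on_nondegenerate_panel(self):
        x, y = _bvn_categorical(0.3, [-0.83, 0.83], [-0.83, 0.83], 300, 8)
        panel = CategoricalPanel(np.column_stack([x, y]), n_categories=3)
        m = sample_moments(panel)
        assert np.all(m.asymptotic_variances > 0)


@pytest.mark.filterwarnings("ignore::RuntimeWarning")  # self-pair hits the rho boundary
def test_sample_moments_stacking_order():
    x, y = _bvn_categorical(0.3, [0.0], [0.0], 500, 9)
    panel = CategoricalPanel(np.column_stack([x, y, x]), n_categories=2)
    m = sample_moments(panel)
    stacked = m.stacked
    assert stacked.size == 3 * 1 + 3
    np.testing.assert_allclose(stacked[:3], m.thresholds.ravel())
    np.testing.assert_allclose(
        stacked[3:], [m.correlations[0, 1], m.correlations[0, 2], m.correlations[1, 2]]
    )
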