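"""DWLS estimator: implied statistics, identification oracle, invariances."""

import numpy as np
import pytest

from catlgm import (
    Condition,
    LgmModelSpec,
    ThresholdSet,
    analytic_sample_moments,
    categorize,
    condition_to_spec,
    fit_dwls,
    fit_panel,
    generate_latent_panel,
    model_implied_statistics,
    population_proportions,
    true_deltas,
)
from catlgm.scaling import ProportionProfile, scale_summary

TRUE_DELTAS = (0.9129, 0.7454, 0.5976)


def _ordinal_conditions():
    return [
        Condition(p, s, c, 1000)
        for p in ("shift", "increase", "decrease")
        for s in ("large", "small")
        for c in (3, 4)
    ]


class TestImpliedStatistics:
    def test_binary_shift_large_thresholds(self, shift_large_spec):
        spec = LgmModelSpec(n_times=4, n_categories=2)
        deltas = np.array([1.0, 1 / np.sqrt(1.2), 1 / np.sqrt(1.8), 1 / np.sqrt(2.8)])
        # generating tau = 0 and alpha00 = -0.6 appear to the fitted model as
        # an invariant threshold at 0.6 (sigma*_1 = 1)
        stats = model_implied_statistics(
            spec, np.array([0.6]), 0.4, 0.5, 0.0, 0.1, deltas
        )
        np.testing.assert_allclose(
            stats[:4], [0.600, 0.183, -0.149, -0.359], atol=5e-4
        )

    def test_no_growth_degenerate_case(self):
        spec = LgmModelSpec(n_times=4, n_categories=3)
        stats = model_implied_statistics(
            spec, np.array([-0.5, 0.5]), 0.0, 0.4, 0.0, 0.0, np.ones(4)
        )
        thr = stats[:8].reshape(4, 2)
        assert np.ptp(thr, axis=0).max() == pytest.approx(0.0, abs=1e-14)
        np.testing.assert_allclose(stats[8:], 0.4, atol=1e-14)

    def test_correlations_symmetric_in_pair_order(self):
        spec = LgmModelSpec(n_times=3, n_categories=2)
        stats = model_implied_statistics(
            spec, np.array([0.1]), 0.2, 0.5, 0.05, 0.1,
            np.array([1.0, 0.9, 0.8]),
        )
        lam = np.arange(3.0)
        cov = 0.5 + np.add.outer(lam, lam) * 0.05 + np.outer(lam, lam) * 0.1
        d = np.array([1.0, 0.9, 0.8])
        expected = (np.outer(d, d) * cov)[np.triu_indices(3, 1)]
        np.testing.assert_allclose(stats[3:], expected, atol=1e-14)


class TestOracleIdentification:
    @pytest.mark.parametrize("cond", _ordinal_conditions(), ids=lambda c: c.label)
    def test_ordinal_population_statistics_recover_parameters(self, cond):
        growth = condition_to_spec(cond)
        moments = analytic_sample_moments(growth, cond.thresholds())
        fit = fit_dwls(moments, LgmModelSpec(4, cond.categories, growth.loadings))
        assert fit.converged
        assert fit.alpha10 == pytest.approx(growth.alpha10, abs=1e-3)
        assert fit.psi11 == pytest.approx(growth.psi11, abs=1e-3)
        np.testing.assert_allclose(fit.deltas[1:], true_deltas(growth)[1:], atol=1e-3)
        assert fit.discrepancy == pytest.approx(0.0, abs=1e-8)

    def test_binary_scaling_calculus_diverges_from_population(self):
        # the binary common-scale SDs built from observed-scale references are
        # humped under the shift pattern, unlike the monotone population SDs
        cond = Condition("shift", "large", 2, 1000)
        growth = condition_to_spec(cond)
        props = population_proportions(growth, cond.thresholds().cuts)
        binary = scale_summary(ProportionProfile(props))
        pop_ratio = 1.0 / true_deltas(growth)  # sqrt(sigma*_t / sigma*_1)
        assert binary.sqrt_s_star[1] > pop_ratio[1]  # exceeds at time 2
        # humped: interior maximum, endpoints lower — while the population
        # ratio increases strictly to 1.673 at the last occasion
        assert binary.sqrt_s_star[1] > binary.sqrt_s_star[0]
        assert binary.sqrt_s_star[3] < binary.sqrt_s_star[2]
        assert pop_ratio[3] > binary.sqrt_s_star.max()
        # the ordinal calculus tracks the population ratio exactly
        props3 = population_proportions(growth, ThresholdSet.for_categories(3).cuts)
        ordinal = scale_summary(ProportionProfile(props3))
        np.testing.assert_allclose(ordinal.sqrt_s_star, pop_ratio, atol=1e-10)


@pytest.fixture(scope="module")
def panel():
    cond = Condition("shift", "large", 3, 500, base_seed=77)
    growth = condition_to_spec(cond)
    latent = generate_latent_panel(growth, 500, cond.seed_sequence(0))
    return categorize(latent, cond.thresholds())


class TestFitInvariances:
    def test_row_permutation_leaves_fit_unchanged(self, panel):
        from catlgm.simulate import CategoricalPanel

        rng = np.random.default_rng(0)
        perm = rng.permutation(panel.n_subjects)
        shuffled = CategoricalPanel(panel.data[perm], panel.n_categories)
        f1, f2 = fit_panel(panel), fit_panel(shuffled)
        assert f1.estimates() == f2.estimates()

    def test_category_reversal_flips_signs(self, panel):
        from catlgm.simulate import CategoricalPanel

        reversed_panel = CategoricalPanel(
            panel.n_categories - 1 - panel.data, panel.n_categories
        )
        f1, f2 = fit_panel(panel), fit_panel(reversed_panel)
        assert f2.alpha10 == pytest.approx(-f1.alpha10, abs=1e-4)
        np.testing.assert_allclose(np.sort(-f2.tau), np.sort(f1.tau), atol=1e-4)
        np.testing.assert_allclose(f2.deltas, f1.deltas, atol=1e-4)

    def test_sampled_recovery_at_large_n(self):
        cond = Condition("shift", "large", 4, 5000, base_seed=5)
        growth = condition_to_spec(cond)
        latent = generate_latent_panel(growth, 5000, cond.seed_sequence(1))
        fit = fit_panel(categorize(latent, cond.thresholds()))
        assert fit.converged
        # ~3 Monte Carlo SEs for alpha10 at this n
        assert fit.alpha10 == pytest.approx(0.40, abs=0.05)
        np.testing.assert_allclose(fit.deltas[1:], TRUE_DELTAS, atol=0.06)

    def test_discrepancy_nonnegative_and_zero_at_truth(self, shift_large_spec):
        cond = Condition("shift", "large", 3, 1000)
        moments = analytic_sample_moments(shift_large_spec, cond.thresholds())
        fit = fit_dwls(moments, LgmModelSpec(4, 3))
        assert fit.discrepancy >= 0
        assert fit.discrepancy == pytest.approx(0.0, abs=1e-10)

    def test_fit_serialization_round_trip(self, panel, tmp_path):
        fit = fit_panel(panel)
        text = fit.to_text()
        values = dict(
            line.split("=", 1) for line in text.strip().splitlines()
        )
        assert values["status"] == fit.status
        assert float(values["alpha10"]) == pytest.approx(fit.alpha10, abs=1e-12)
        assert float(values["delta_4"]) == pytest.approx(fit.deltas[3], abs=1e-12)
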