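"""Probabilistic sensitivity analysis, CEAC and one-way DSA."""

import numpy as np
import pytest

from pgxcea import (
    ceac,
    compare_strategies,
    default_registry,
    one_way_dsa,
    probability_cost_effective,
    run_psa,
    sample_parameters,
)
from pgxcea.parameters import DistributionSpec, ParameterEntry, ParameterRegistry


def all_fixed_registry():
    reg = default_registry()
    entries = {
        name: ParameterEntry(e.mean, DistributionSpec("fixed"), False)
        for name, e in reg.items()
    }
    return ParameterRegistry(entries)


class TestSampling:
    def test_sample_means_match_analytic_means(self, registry):
        draws = sample_parameters(registry, 100_000, seed=123)
        for name, entry in registry.items():
            if entry.spec.kind == "fixed":
                assert np.all(draws[name] == entry.mean)
            else:
                from pgxcea import distribution_mean

                analytic = distribution_mean(entry.spec)
                se = draws[name].std() / np.sqrt(len(draws))
                assert abs(draws[name].mean() - analytic) < 4 * se, name

    def test_fixed_registry_draws_are_constant(self):
        draws = sample_parameters(all_fixed_registry(), 50, seed=1)
        assert (draws.nunique() == 1).all()

    def test_reproducible_given_seed(self, registry):
        a = sample_parameters(registry, 1000, seed=7)
        b = sample_parameters(registry, 1000, seed=7)
        assert a.equals(b)

    def test_invalid_n_rejected(self, registry):
        with pytest.raises(ValueError):
            sample_parameters(registry, 0, seed=1)


class TestRunPSA:
    def test_bitwise_reproducibility(self, params, registry):
        a = run_psa(params, registry, 500, seed=11)
        b = run_psa(params, registry, 500, seed=11)
        assert np.array_equal(a.cost_pgx, b.cost_pgx)
        assert np.array_equal(a.qaly_soc, b.qaly_soc)

    def test_single_draw_is_deterministic(self, params, registry):
        a = run_psa(params, registry, 1, seed=3)
        assert a.n_iter == 1 and a.cost_soc.shape == (1,)

    def test_psa_means_converge_to_deterministic_base_case(
        self, params, registry, combined_panel
    ):
        """With near-linear structure the PSA mean increments approach the
        point-estimate increments."""
        draws = run_psa(params, registry, 50_000, seed=21)
        ce = compare_strategies(params, combined_panel)
        assert draws.delta_qaly.mean() == pytest.approx(ce.delta_qaly, rel=0.05)
        assert draws.delta_cost.mean() == pytest.approx(ce.delta_cost, rel=0.10)

    def test_fixed_panel_overrides_sampled_performance(self, params, registry):
        from pgxcea import PanelPerformance

        draws = run_psa(
            params, registry, 200, seed=5, panel=PanelPerformance(0.36, 0.89)
        )
        assert np.all(draws.parameters["sensitivity"] == 0.36)
        assert np.all(draws.parameters["specificity"] == 0.89)


@pytest.fixture(scope="module")
def draws():
    from pgxcea import ModelParameters

    return run_psa(ModelParameters(), default_registry(), 20_000, seed=17)


class TestCEAC:
    def test_probabilities_bounded_and_monotone(self, draws):
        curve = ceac(draws)
        assert np.all(curve.probability >= 0) and np.all(curve.probability <= 1)
        # dQALY > 0 in essentially all draws, so the curve is nondecreasing
        assert np.all(np.diff(curve.probability) >= -1e-12)

    def test_at_zero_wtp_equals_cost_saving_fraction(self, draws):
        curve = ceac(draws, [0.0, 30_000.0])
        assert curve.probability[0] == pytest.approx(
            np.mean(draws.delta_cost < 0), abs=1e-12
        )

    def test_limit_is_one_when_qaly_gain_almost_sure(self, draws):
        p_inf = probability_cost_effective(draws, 1e9)
        assert p_inf == pytest.approx(np.mean(draws.delta_qaly > 0), abs=1e-12)

    def test_scatter_quadrants_partition(self, draws):
        quadrants = (
            np.mean((draws.delta_qaly >= 0) & (draws.delta_cost >= 0))
            + np.mean((draws.delta_qaly >= 0) & (draws.delta_cost < 0))
            + np.mean((draws.delta_qaly < 0) & (draws.delta_cost >= 0))
            + np.mean((draws.delta_qaly < 0) & (draws.delta_cost < 0))
        )
        assert quadrants == pytest.approx(1.0, abs=1e-12)

    def test_empty_grid_rejected(self, draws):
        with pytest.raises(ValueError):
            ceac(draws, [])


class TestOneWayDSA:
    def test_icer_strictly_decreasing_in_sensitivity(self, params, combined_panel):
        res = one_way_dsa(params, combined_panel, "sensitivity", np.linspace(0.2, 0.8, 13))
        assert np.all(np.diff(res.icer) < 0)

    def test_icer_constant_in_specificity(self, params, combined_panel):
        res = one_way_dsa(
            params, combined_panel, "specificity", np.linspace(0.70, 0.99, 13)
        )
        assert np.ptp(res.icer) == pytest.approx(0.0, abs=1e-9)

    def test_single_point_grid_recovers_base_case(self, params, combined_panel):
        base = compare_strategies(params, combined_panel)
        res = one_way_dsa(
            params, combined_panel, "sensitivity", [combined_panel.sensitivity]
        )
        assert res.icer[0] == pytest.approx(base.icer, rel=1e-12)

    def test_model_parameter_sweep(self, params, combined_panel):
        res = one_way_dsa(
            params, combined_panel, "cost_genetic_test", [0.0, 110.0, 300.0]
        )
        assert np.isnan(res.icer[0]) or res.icer[0] <= 0  # dominant at zero cost
        assert np.all(np.diff(res.icer[1:]) > 0)

    def test_unknown_parameter_rejected(self, params, combined_panel):
        with pytest.raises(ValueError):
            one_way_dsa(params, combined_panel, "not_a_parameter", [0.1, 0.2])

    def test_non_increasing_grid_rejected(self, params, combined_panel):
        with pytest.raises(ValueError):
            one_way_dsa(params, combined_panel, "sensitivity", [0.5, 0.4])
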