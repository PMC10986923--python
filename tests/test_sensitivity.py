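"""Tornado analysis and the four scenario analyses."""

from dataclasses import replace

import numpy as np
import pytest

from hooftrim.cohort import run_cohort
from hooftrim.economics import compare_strategies
from hooftrim.parameters import SensitivityBound
from hooftrim.sensitivity import (
    apply_parameter,
    one_way_sensitivity,
    reference_bounds,
    scenario_herd_size_sweep,
    scenario_no_quota,
    scenario_random_selection,
    scenario_targeting_sweep,
    solve_nonulcer_trim_probability,
)


@pytest.fixture(scope="module")
def tornado(reference):
    return one_way_sensitivity(reference)


class TestTornado:
    def test_widest_bars_are_size_trim_probability_prevalence(self, tornado):
        top3 = {e.param_name for e in tornado[:3]}
        assert top3 == {"herd_size", "trim_probability", "prevalence"}

    def test_sorted_by_descending_width(self, tornado):
        widths = [e.range_width for e in tornado]
        assert widths == sorted(widths, reverse=True)

    def test_degenerate_bounds_zero_width(self, reference):
        ref_diff = compare_strategies(reference).difference
        bounds = [SensitivityBound("trim_cost", 15.02, 15.02)]
        (entry,) = one_way_sensitivity(reference, bounds)
        assert entry.range_width == pytest.approx(0.0, abs=1e-9)
        assert entry.difference_at_low == pytest.approx(ref_diff)

    def test_herd_size_near_proportional(self, tornado):
        entry = next(e for e in tornado if e.param_name == "herd_size")
        ratio = entry.difference_at_high / entry.difference_at_low
        assert ratio == pytest.approx(10.0, rel=0.15)

    def test_benefit_rows_have_zero_width(self, tornado):
        """Milk and cattle sales are identical in both arms, so varying them
        cannot move the between-strategy difference."""
        for name in ("milk_sales", "cattle_sales"):
            entry = next(e for e in tornado if e.param_name == name)
            assert entry.range_width == pytest.approx(0.0, abs=1e-9)

    def test_block_bounds_recompute_expected_cost(self, reference):
        cfg = apply_parameter(reference, "block_probability", 0.5)
        assert cfg.cost("block_cost") == pytest.approx(28.88 * 0.5)
        cfg = apply_parameter(reference, "block_unit_cost", 30.80)
        assert cfg.cost("block_cost") == pytest.approx(30.80 * 0.70)

    def test_labor_bound_moves_both_session_costs(self, reference):
        cfg = apply_parameter(reference, "labor_cost", 13.39)
        assert cfg.cost("labor_partial") == pytest.approx(13.39)
        assert cfg.cost("labor_whole") == pytest.approx(13.39 / 4.5, abs=0.01)

    def test_unknown_parameter_rejected(self, reference):
        with pytest.raises(ValueError, match="unknown"):
            one_way_sensitivity(reference, [SensitivityBound("culling_rate", 0, 1)])


class TestBudgetSolver:
    def test_reference_targeting_recovers_printed_healthy_probability(self, reference):
        ph = solve_nonulcer_trim_probability(0.54, 324.0, reference)
        assert ph == pytest.approx(0.1699, abs=0.002)

    def test_no_disease_budget_forces_exact_rate(self, reference):
        cfg = reference.with_probability("prevalence", 0.0)
        cfg = cfg.with_probability("incidence_risk", 0.0)
        ph = solve_nonulcer_trim_probability(0.18, 324.0, cfg)
        assert ph == pytest.approx(0.18, abs=1e-9)

    def test_full_targeting_lowers_healthy_probability(self, reference):
        ph = solve_nonulcer_trim_probability(1.0, 324.0, reference)
        assert ph < 0.1699
        cfg = reference.with_probability("trim_probability_ulcer", 1.0)
        cfg = cfg.with_probability("trim_probability_healthy", ph)
        assert run_cohort(cfg, "partial").expected_trims_total == pytest.approx(324.0, abs=0.01)

    def test_infeasible_budget_rejected(self, reference):
        with pytest.raises(ValueError, match="infeasible"):
            solve_nonulcer_trim_probability(0.54, 5000.0, reference)


class TestScenarios:
    def test_scenario1_flips_preference_to_whole_herd(self, reference):
        result = scenario_random_selection(reference, 2000, seed=1)
        assert result.stats["fraction_whole_preferred"] > 0.9
        assert 344 < result.stats["mean_whole_minus_partial"] < 6409

    def test_scenario1_restoring_targeting_recovers_reference(self, reference, reference_psa):
        from hooftrim.sensitivity import random_selection_config
        from hooftrim.psa import run_psa

        cfg = random_selection_config(reference)
        restored = replace(
            cfg,
            policy_ulcer_param="trim_probability_ulcer",
            policy_healthy_param="trim_probability_healthy",
        )
        result = run_psa(restored, 2000, seed=1)
        assert np.array_equal(result.differences, reference_psa.differences)

    def test_scenario2_budget_conserved_and_monotone(self, reference):
        result = scenario_targeting_sweep(reference)
        trims = result.table.expected_trims
        assert np.allclose(trims, 324.0, atol=0.01)
        diffs = result.table.difference.to_numpy()
        assert np.all(np.diff(diffs) > 0)

    def test_scenario2_reference_level_matches_deterministic(self, reference):
        result = scenario_targeting_sweep(reference)
        at_054 = result.table.set_index("p_trim_ulcer").loc[0.54, "difference"]
        assert at_054 == pytest.approx(compare_strategies(reference).difference, rel=0.01)

    def test_scenario2_psa_means_negative_at_random_targeting(self, reference):
        result = scenario_targeting_sweep(reference, n_iter=400, seed=2)
        means = result.table.mean_difference_psa.to_numpy()
        assert means[0] < 0  # random selection: whole herd preferred on average
        assert np.all(np.diff(means) > 0)

    def test_scenario3_linear_in_herd_size(self, reference):
        result = scenario_herd_size_sweep(reference)
        assert result.stats["r_squared"] > 0.999
        assert result.stats["slope"] > 0
        diffs = result.table.set_index("herd_size").difference
        assert diffs.loc[500] > diffs.loc[50]

    def test_scenario3_intercept_is_pure_labor_asymmetry(self, reference):
        """With both labor costs zeroed every component scales with herd size,
        so the fitted intercept collapses to zero."""
        cfg = reference.with_cost("labor_partial", 0.0).with_cost("labor_whole", 0.0)
        result = scenario_herd_size_sweep(cfg)
        assert result.stats["intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_scenario4_dominance_and_ci(self, reference):
        result = scenario_no_quota(reference, 2000, seed=1)
        assert result.stats["fraction_partial_preferred"] == 1.0
        assert 2407 < result.stats["mean_difference"] < 5412

    def test_scenario4_below_reference_with_cheaper_unit(self, reference, reference_psa):
        """Milk loss (73.50) is cheaper than the additional cow (101.63) per
        ulcer cow-cycle, so the no-quota difference must be smaller."""
        result = scenario_no_quota(reference, 2000, seed=1)
        assert result.stats["mean_difference"] < reference_psa.mean_difference

    def test_scenario4_equal_unit_cost_reproduces_reference(self, reference):
        """Pricing milk loss at the additional-cow unit cost makes the two
        production-cost modes equivalent (up to the sub-dollar Normal noise
        of the independently drawn unit price)."""
        from dataclasses import replace as dreplace
        from hooftrim.psa import run_psa

        costs = dict(reference.costs)
        costs["milk_loss_cost"] = dreplace(
            costs["additional_cow_cost"], name="milk_loss_cost"
        )
        cfg = dreplace(reference, costs=costs)
        no_quota = scenario_no_quota(cfg, 200, seed=1)
        ref = run_psa(reference, 200, seed=1)
        assert np.allclose(
            no_quota.table.difference.to_numpy(), ref.differences, atol=25.0
        )
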