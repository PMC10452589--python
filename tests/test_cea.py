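"""Incremental analysis, dominance, PSA sampling, CEAC and deterministic SA."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metasurv import run_strategy
from metasurv.cea import (ABS_DOMINATED, EXT_DOMINATED, REFERENCE, ceac,
                          ceac_maximizer, dsa_presets, frontier,
                          frontier_oracle, incremental_table, one_way_dsa,
                          run_psa, run_scenario, sample_psa_config,
                          scenario_table, two_way_dsa)
from metasurv.parameters import PsaDistribution, default_config, set_param


def _by_code(rows):
    return {r.strategy_code: r for r in rows}


class TestIncrementalTable:
    def test_absolute_dominance_two_strategies(self):
        rows = _by_code(incremental_table([("a", 100.0, 1.0), ("b", 50.0, 2.0)]))
        assert rows["a"].status == ABS_DOMINATED
        assert rows["b"].status == REFERENCE

    def test_straight_line_retains_equal_icers(self):
        rows = incremental_table([("a", 0.0, 0.0), ("b", 100.0, 1.0),
                                  ("c", 200.0, 2.0)])
        assert [r.status for r in rows] == [REFERENCE, "frontier", "frontier"]
        assert rows[1].icer == rows[2].icer == pytest.approx(100.0)

    def test_extended_dominance_elimination(self):
        # b's ICER (100) exceeds c's ICER vs a (50): b is extended dominated
        rows = _by_code(incremental_table([
            ("a", 0.0, 0.0), ("b", 100.0, 1.0), ("c", 200.0, 4.0)]))
        assert rows["b"].status == EXT_DOMINATED
        assert rows["c"].icer == pytest.approx(50.0)  # recomputed vs a

    def test_single_strategy_is_reference(self):
        rows = incremental_table([("only", 10.0, 1.0)])
        assert rows[0].status == REFERENCE and rows[0].icer is None

    def test_duplicate_codes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            incremental_table([("a", 1.0, 1.0), ("a", 2.0, 2.0)])

    def test_frontier_icers_nondecreasing(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(2, 8)
            pts = [(f"s{i}", float(rng.uniform(0, 1e4)), float(rng.uniform(0, 2)))
                   for i in range(n)]
            rows = incremental_table(pts)
            icers = [r.icer for r in rows if r.icer is not None]
            assert all(a <= b + 1e-9 for a, b in zip(icers, icers[1:]))

    def test_adjacent_row_convention_reported(self):
        rows = incremental_table([("a", 0.0, 0.0), ("b", 10.0, 2.0),
                                  ("c", 15.0, 1.0)])
        c = _by_code(rows)["c"]
        assert c.status == ABS_DOMINATED
        assert c.delta_cost_adjacent == pytest.approx(5.0)
        assert c.delta_effect_adjacent == pytest.approx(-1.0)


class TestFrontierOracle:
    def test_single_strategy(self):
        assert frontier_oracle([("only", 5.0, 1.0)]) == {"only"}

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_incremental_survivors_on_random_instances(self, data):
        n = data.draw(st.integers(2, 8))
        pts = [(f"s{i}",
                data.draw(st.floats(0, 10_000, allow_nan=False)),
                data.draw(st.floats(0, 3, allow_nan=False)))
               for i in range(n)]
        # generic position: skip degenerate exact ties
        if len({round(c, 9) for _, c, _ in pts}) < n or \
                len({round(e, 9) for _, _, e in pts}) < n:
            return
        assert set(frontier(incremental_table(pts))) == frontier_oracle(pts)


class TestPsaSampling:
    def test_all_fixed_config_passes_through(self, base_config):
        cfg = set_param(base_config, "psa_distributions",
                        {k: PsaDistribution("fixed")
                         for k in base_config.psa_distributions})
        rng = np.random.default_rng(0)
        assert sample_psa_config(cfg, rng) == cfg

    def test_beta_moment_match_ct_sensitivity(self, base_config):
        rng = np.random.default_rng(1)
        draws = np.array([sample_psa_config(base_config, rng)
                          .tests.ct.sensitivity.value for _ in range(3000)])
        assert abs(draws.mean() - 0.83) < 0.01
        inside = np.mean((draws >= 0.68) & (draws <= 0.98))
        assert 0.90 <= inside <= 0.99  # ~95% of mass inside the printed range
        assert np.all((draws >= 0) & (draws <= 1))

    def test_gamma_costs_stay_positive(self, base_config):
        rng = np.random.default_rng(2)
        draws = np.array([sample_psa_config(base_config, rng).costs.colonoscopy
                          for _ in range(500)])
        assert np.all(draws > 0)
        assert draws.std() > 0

    def test_degenerate_and_fixed_parameters_unchanged(self, base_config):
        rng = np.random.default_rng(3)
        for _ in range(20):
            cfg = sample_psa_config(base_config, rng)
            assert cfg.utilities == base_config.utilities
            assert cfg.costs.cea_test == 60.62
            assert cfg.costs.ct_scan == 300.15  # gamma with sd 0: point mass
            assert cfg.tests.colonoscopy.specificity.value == 1.00  # boundary beta
            assert cfg.clinical.asymptomatic_metastasectomy_rate == 0.23
            assert cfg.clinical.mean_months_undetected_to_symptomatic.value >= 1.0

    def test_infeasible_beta_sd_clamped_with_warning(self, base_config, caplog):
        cfg = set_param(base_config, "psa_distributions", {
            "tests.ct.sensitivity": PsaDistribution("beta", 0.83, 0.9)})
        with caplog.at_level(logging.WARNING, logger="metasurv.cea"):
            out = sample_psa_config(cfg, np.random.default_rng(4))
        assert "clamped" in caplog.text
        assert 0.0 <= out.tests.ct.sensitivity.value <= 1.0


@pytest.fixture(scope="module")
def fixed_config():
    cfg = default_config()
    return set_param(cfg, "psa_distributions",
                     {k: PsaDistribution("fixed")
                      for k in cfg.psa_distributions})


class TestPsaAndCeac:
    def test_single_draw_all_fixed_equals_base_case(self, fixed_config):
        psa = run_psa(fixed_config, n_draws=1, n_patients_per_draw=400, seed=17)
        for si, code in enumerate(psa.strategies):
            base = run_strategy(fixed_config, code, n_patients=400, seed=17)
            assert psa.cost[0, si] == base.mean_cost
            assert psa.qaly[0, si] == base.mean_qaly

    def test_fixed_distributions_give_identical_parameter_draws(self, fixed_config):
        psa = run_psa(fixed_config, n_draws=3, n_patients_per_draw=150, seed=5)
        # patient noise differs across draws, but strategies stay ordered by cost
        assert psa.cost.shape == (3, 4)

    def test_ceac_probabilities_sum_to_one(self, base_config):
        psa = run_psa(base_config, n_draws=6, n_patients_per_draw=150, seed=9)
        curves = ceac(psa, (0.0, 50_000.0, 500_000.0))
        sums = curves.groupby("wtp")["probability_cost_effective"].sum()
        assert np.allclose(sums.values, 1.0)

    def test_ceac_single_strategy_is_unity(self, base_config):
        psa = run_psa(base_config, n_draws=3, n_patients_per_draw=100, seed=9,
                      strategies=("q12",))
        curves = ceac(psa, (50_000.0,))
        assert np.allclose(curves["probability_cost_effective"], 1.0)

    def test_ceac_invariant_to_strategy_order(self, base_config):
        a = ceac(run_psa(base_config, n_draws=4, n_patients_per_draw=120, seed=2,
                         strategies=("q12", "q3_q12")), (50_000.0,))
        b = ceac(run_psa(base_config, n_draws=4, n_patients_per_draw=120, seed=2,
                         strategies=("q3_q12", "q12")), (50_000.0,))
        for code in ("q12", "q3_q12"):
            pa = a[a.strategy == code]["probability_cost_effective"].iloc[0]
            pb = b[b.strategy == code]["probability_cost_effective"].iloc[0]
            assert pa == pytest.approx(pb)

    def test_deterministic_nmb_choice_matches_frontier_segment(self, fixed_config):
        """On point-mass draws the CEAC winner at a threshold equals the
        frontier strategy whose ICER segment brackets that threshold."""
        results = [run_strategy(fixed_config, c, n_patients=3000, seed=17)
                   for c in ("q12", "q6_q12", "q6", "q3_q12")]
        rows = incremental_table(results)
        surviving = [r for r in rows if r.status in (REFERENCE, "frontier")]
        psa = run_psa(fixed_config, n_draws=1, n_patients_per_draw=3000, seed=17)
        for lam in (1_000.0, 50_000.0, 2_000_000.0):
            nmb_best = max(surviving,
                           key=lambda r: lam * r.effect - r.cost).strategy_code
            curves = ceac(psa, (lam,))
            assert ceac_maximizer(curves, lam) == nmb_best


class TestDeterministicSA:
    def test_base_value_scenario_equals_base_case(self, base_config):
        path = "clinical.mean_months_undetected_to_symptomatic"
        table = one_way_dsa(base_config, path, [4.0], n_patients=500, seed=17)
        base = {c: run_strategy(base_config, c, n_patients=500, seed=17)
                for c in ("q12", "q6_q12", "q6", "q3_q12")}
        for _, row in table.iterrows():
            assert row["cost"] == base[row["strategy"]].mean_cost
            assert row["qaly"] == base[row["strategy"]].mean_qaly

    def test_unknown_parameter_path_is_informative(self, base_config):
        from metasurv.parameters import ConfigError

        with pytest.raises(ConfigError, match="known paths"):
            run_scenario(base_config, {"clinical.not_a_knob": 1.0},
                         n_patients=10, seed=0)

    def test_presets_cover_published_scenarios(self, base_config):
        presets = dsa_presets(base_config)
        assert {"time_to_symptomatic", "resection_rates"} <= set(presets)
        labels = [lbl for lbl, _ in presets["resection_rates"]]
        assert len(labels) == 2
        ov = dict(presets["resection_rates"])[labels[0]]
        assert ov["clinical.asymptomatic_metastasectomy_rate"] == \
            pytest.approx(0.23 * 0.75)
        assert ov["clinical.symptomatic_metastasectomy_rate"] == \
            pytest.approx(0.05 * 1.25)

    def test_scenario_table_shape_and_reference(self, base_config):
        table = scenario_table(
            base_config, dsa_presets(base_config)["resection_rates"],
            n_patients=400, seed=17)
        assert len(table) == 8  # 2 scenarios x 4 strategies
        for _, row in table.iterrows():
            if row["strategy"] == "q12":
                assert math.isnan(row["icer_vs_q12"]) or row["icer_vs_q12"] is None

    def test_two_way_single_cell_matches_base_preference(self, base_config):
        grid = two_way_dsa(
            base_config,
            "clinical.mean_months_undetected_to_symptomatic", [4.0],
            "clinical.asymptomatic_metastasectomy_rate", [0.23],
            wtp=50_000.0, n_patients=800, seed=17)
        assert len(grid) == 1
        results = [run_strategy(base_config, c, n_patients=800, seed=17)
                   for c in ("q12", "q6_q12", "q6", "q3_q12")]
        best = max(results, key=lambda r: 50_000.0 * r.mean_qaly - r.mean_cost)
        assert grid["preferred_strategy"].iloc[0] == best.strategy_code

    def test_two_way_noop_parameter_gives_constant_grid(self, base_config):
        grid = two_way_dsa(base_config, "costs.cea_test", [60.62, 60.62],
                           "utilities.ned", [0.78, 0.78],
                           n_patients=300, seed=17)
        assert grid["preferred_strategy"].nunique() == 1
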