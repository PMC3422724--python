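"""One-way analysis, PSA sampling, threshold scans and scenarios."""

import numpy as np
import pytest

from rtcea.cea import DOMINATED, REFERENCE
from rtcea.markov import run_all
from rtcea.parameters import ParameterBundle, UtilitySet
from rtcea.sensitivity import (
    ParamSpec,
    beta_params,
    default_param_specs,
    draw_parameters,
    gamma_params,
    one_way,
    run_psa,
    scenario_bundle,
    scenario_run,
    threshold_scan,
    tornado,
    _set_param,
)


class TestMethodOfMoments:
    def test_beta_closed_form(self):
        assert beta_params(0.2, 0.1) == pytest.approx((3.0, 12.0))

    def test_beta_mean_and_sd_recovered(self):
        a, b = beta_params(0.272, 0.232)
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert mean == pytest.approx(0.272)
        assert np.sqrt(var) == pytest.approx(0.232)

    def test_beta_infeasible_variance_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            beta_params(0.01, 0.2)

    def test_gamma_fifty_percent_se_gives_shape_four(self):
        shape, scale = gamma_params(20_889.0)
        assert shape == pytest.approx(4.0)
        assert scale == pytest.approx(5_222.25)


class TestDrawParameters:
    def test_all_ses_zero_returns_base_bundle(self, bundle, rng):
        utilities = UtilitySet(values=dict(bundle.utilities.values),
                               se={s: 0.0 for s in bundle.utilities.se})
        arms = [a.model_copy(update={"toxicity": a.toxicity.model_copy(
                    update={"gu_se": 0.0, "gi_se": 0.0, "sd_se": 0.0})})
                for a in bundle.arms]
        frozen = ParameterBundle(bundle.config, arms, utilities, bundle.costs)
        drawn = draw_parameters(frozen, rng, cost_se_fraction=0.0)
        assert drawn == frozen

    def test_reproducible_given_seed(self, bundle):
        d1 = draw_parameters(bundle, np.random.default_rng(7))
        d2 = draw_parameters(bundle, np.random.default_rng(7))
        assert d1 == d2
        d3 = draw_parameters(bundle, np.random.default_rng(8))
        assert d3 != d1

    def test_pt_sd_tied_to_imrt_draw(self, bundle, rng):
        drawn = draw_parameters(bundle, rng, tie_pt_sd_to_imrt=True)
        assert drawn.arm("PT").toxicity.sd == drawn.arm("IMRT").toxicity.sd

    def test_pt_sd_untied_draws_independently(self, bundle, rng):
        drawn = draw_parameters(bundle, rng, tie_pt_sd_to_imrt=False)
        assert drawn.arm("PT").toxicity.sd != drawn.arm("IMRT").toxicity.sd

    def test_fixed_quantities_stay_fixed(self, bundle, rng):
        drawn = draw_parameters(bundle, rng)
        assert drawn.utilities.values["none"] == 1.0
        assert drawn.utilities.values["death"] == 0.0
        for arm in drawn.arms:
            assert arm.treatment.treatment_mortality == 0.0
        assert (drawn.costs.oxybutynin_days_per_year
                == bundle.costs.oxybutynin_days_per_year)

    def test_infeasible_beta_falls_back_with_warning(self, bundle, rng,
                                                     caplog):
        arms = [bundle.arms[0].model_copy(update={
            "toxicity": bundle.arms[0].toxicity.model_copy(
                update={"gu": 0.01, "gu_se": 0.5})})] + list(bundle.arms[1:])
        odd = ParameterBundle(bundle.config, arms, bundle.utilities,
                              bundle.costs)
        with caplog.at_level("WARNING"):
            drawn = draw_parameters(odd, rng)
        assert drawn.arms[0].toxicity.gu == 0.01
        assert "infeasible" in caplog.text

    def test_draws_stay_in_unit_interval(self, bundle):
        rng = np.random.default_rng(3)
        for _ in range(100):
            drawn = draw_parameters(bundle, rng)
            for arm in drawn.arms:
                for ch in ("GU", "GI", "SD"):
                    assert 0.0 <= arm.toxicity.prob(ch) <= 1.0
            assert all(0.0 <= v <= 1.0
                       for v in drawn.utilities.values.values())


class TestOneWay:
    def test_width_zero_equals_base(self, bundle, life_table, bg):
        spec = ParamSpec(path="arm:SBRT:toxicity:GU", base=0.040, low=0.040,
                         high=0.040, distribution="beta", se=0.0)
        low, high = one_way(spec, bundle, life_table, bg)
        base = {r.strategy: r for r in
                __import__("rtcea").cea.icer_table(
                    run_all(bundle, life_table, bg))}
        for rows in (low, high):
            for r in rows:
                assert r.cost == pytest.approx(base[r.strategy].cost)
                assert r.qaly == pytest.approx(base[r.strategy].qaly)

    def test_sbrt_cost_upper_bound_adds_quarter(self, bundle, life_table, bg):
        spec = ParamSpec(path="cost:treatment:SBRT", base=20_889.0,
                         low=0.75 * 20_889.0, high=1.25 * 20_889.0,
                         distribution="gamma", se=0.5 * 20_889.0)
        _, high = one_way(spec, bundle, life_table, bg)
        base = {r.strategy: r.cost for r in
                __import__("rtcea").cea.icer_table(
                    run_all(bundle, life_table, bg))}
        sbrt_high = next(r for r in high if r.strategy == "SBRT")
        assert sbrt_high.cost - base["SBRT"] == pytest.approx(
            0.25 * 20_889.0)

    def test_cost_variations_keep_sbrt_dominant(self, bundle, life_table, bg):
        """Moving any cost by +/-25% never changes the dominance picture:
        SBRT stays the cheapest strategy with the most QALYs. (Toxicity
        confidence intervals are wide enough to flip the QALY ordering —
        the upper SBRT SD bound exceeds the +43% flip point — so only
        costs admit a blanket robustness claim.)"""
        specs = [s for s in default_param_specs(bundle)
                 if s.distribution == "gamma"]
        assert specs
        for spec in specs:
            for rows in one_way(spec, bundle, life_table, bg):
                by_name = {r.strategy: r.status for r in rows}
                assert by_name["SBRT"] == REFERENCE
                assert by_name["IMRT"] == DOMINATED
                assert by_name["PT"] == DOMINATED

    def test_unknown_path_raises(self, bundle):
        with pytest.raises(KeyError):
            _set_param(bundle, "arm:SBRT:nonsense:GU", 0.1)
        with pytest.raises(KeyError):
            _set_param(bundle, "cost:unit:bogus_fee", 1.0)

    def test_tornado_ranks_by_spread(self, bundle, life_table, bg):
        specs = default_param_specs(bundle)[:5]
        df = tornado(bundle, life_table, bg, specs=specs)
        assert list(df.columns) == ["parameter", "low_value", "high_value",
                                    "inmb_low", "inmb_high", "spread"]
        assert df["spread"].is_monotonic_decreasing


class TestPSA:
    def test_reproducible_bitwise(self, bundle, life_table, bg):
        a = run_psa(bundle, life_table, bg, n_iter=40, seed=5)
        b = run_psa(bundle, life_table, bg, n_iter=40, seed=5)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)

    def test_seed_changes_samples(self, bundle, life_table, bg):
        a = run_psa(bundle, life_table, bg, n_iter=40, seed=5)
        b = run_psa(bundle, life_table, bg, n_iter=40, seed=6)
        assert not np.array_equal(a.costs, b.costs)

    def test_degenerate_single_iteration_matches_deterministic(
            self, bundle, life_table, bg):
        utilities = UtilitySet(values=dict(bundle.utilities.values),
                               se={s: 0.0 for s in bundle.utilities.se})
        arms = [a.model_copy(update={"toxicity": a.toxicity.model_copy(
                    update={"gu_se": 0.0, "gi_se": 0.0, "sd_se": 0.0})})
                for a in bundle.arms]
        frozen = ParameterBundle(bundle.config, arms, utilities, bundle.costs)
        # cost draws stay stochastic, so only the QALY side is degenerate
        psa = run_psa(frozen, life_table, bg, n_iter=1, seed=0)
        det = {r.name: r for r in run_all(frozen, life_table, bg)}
        assert psa.qalys[0, 0] == pytest.approx(det["SBRT"].qaly)
        p = psa.pairwise_probability("SBRT", "IMRT", 50_000.0)
        assert p in (0.0, 0.5, 1.0)

    def test_estimates_converge_with_iterations(self, bundle, life_table, bg):
        small = run_psa(bundle, life_table, bg, n_iter=400, seed=12)
        large = run_psa(bundle, life_table, bg, n_iter=1600, seed=13)
        for comparator in ("IMRT", "PT"):
            p_small = small.pairwise_probability("SBRT", comparator, 50_000.0)
            p_large = large.pairwise_probability("SBRT", comparator, 50_000.0)
            se = np.sqrt(p_large * (1 - p_large) / 400)
            assert abs(p_small - p_large) <= 2.5 * se

    def test_invalid_iteration_count(self, bundle, life_table, bg):
        with pytest.raises(ValueError):
            run_psa(bundle, life_table, bg, n_iter=0, seed=0)


class TestThresholdScan:
    def test_multiplier_one_changes_nothing(self, bundle, life_table, bg):
        from rtcea.sensitivity import _scale_toxicity

        scaled = _scale_toxicity(bundle, "SBRT", ("GU", "GI", "SD"), 1.0)
        base = {r.name: r for r in run_all(bundle, life_table, bg)}
        after = {r.name: r for r in run_all(scaled, life_table, bg)}
        for name in base:
            assert after[name].qaly == pytest.approx(base[name].qaly)
            assert after[name].cost == pytest.approx(base[name].cost)

    def test_sbrt_outcomes_monotone_in_multiplier(self, bundle, life_table,
                                                  bg):
        from rtcea.sensitivity import _scale_toxicity

        qalys, costs = [], []
        for m in (1.0, 1.5, 2.0):
            scaled = _scale_toxicity(bundle, "SBRT", ("GU", "GI", "SD"), m)
            result = next(r for r in run_all(scaled, life_table, bg)
                          if r.name == "SBRT")
            qalys.append(result.qaly)
            costs.append(result.cost)
        assert qalys[0] > qalys[1] > qalys[2]
        assert costs[0] < costs[1] < costs[2]

    def test_unreachable_criterion_returns_none(self, bundle, life_table, bg):
        assert threshold_scan(bundle, life_table, bg, channels=("GU",),
                              criterion="qaly_flip",
                              max_multiplier=1.05) is None

    def test_probabilities_clamped_at_one(self, bundle, life_table, bg):
        from rtcea.sensitivity import _scale_toxicity

        scaled = _scale_toxicity(bundle, "SBRT", ("SD",), 50.0)
        assert scaled.arm("SBRT").toxicity.sd == 1.0


class TestScenarios:
    def test_gi_annual_mode_flag_flipped(self, bundle):
        scen = scenario_bundle("gi_annual_cost", bundle)
        assert scen.costs.gi_cost_mode == "annual"
        assert scen.arms == bundle.arms

    def test_gi_annual_keeps_sbrt_dominant(self, bundle, life_table, bg):
        tables = scenario_run("gi_annual_cost", bundle, life_table, bg)
        for rows in tables.values():
            by_name = {r.strategy: r.status for r in rows}
            assert by_name["SBRT"] == REFERENCE
            assert by_name["IMRT"] == DOMINATED
            assert by_name["PT"] == DOMINATED

    def test_pt_sd_set_to_sbrt(self, bundle):
        scen = scenario_bundle("pt_sd_equals_sbrt", bundle)
        assert scen.arm("PT").toxicity.sd == bundle.arm("SBRT").toxicity.sd
        assert scen.arm("PT").toxicity.sd_se == bundle.arm(
            "SBRT").toxicity.sd_se
        assert scen.arm("IMRT") == bundle.arm("IMRT")

    def test_pt_scenario_noop_when_rates_already_equal(self, bundle,
                                                       life_table, bg):
        arms = [a if a.name != "SBRT" else a.model_copy(update={
            "toxicity": a.toxicity.model_copy(update={
                "sd": bundle.arm("PT").toxicity.sd,
                "sd_se": bundle.arm("PT").toxicity.sd_se})})
            for a in bundle.arms]
        tied = ParameterBundle(bundle.config, arms, bundle.utilities,
                               bundle.costs)
        scen = scenario_bundle("pt_sd_equals_sbrt", tied)
        assert scen.arms == tied.arms

    def test_unknown_scenario_rejected(self, bundle):
        with pytest.raises(ValueError):
            scenario_bundle("no_such_scenario", bundle)
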