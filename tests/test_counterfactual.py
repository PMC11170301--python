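"""Counterfactual redistribution, NNT arithmetic, scenario builders, sweeps."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import erpo_avert as ea
from erpo_avert.method_model import DEFAULT_METHODS


def _two_method_scenario():
    tax = ea.MethodTaxonomy(("a", "b"))
    return ea.Scenario(
        n_subjects=100,
        deaths=ea.DeathTally({"a": 1, "b": 1}, taxonomy=tax),
        cfr=ea.CFRTable({"a": 0.5, "b": 0.1}, taxonomy=tax),
        counterfactual=ea.MethodDistribution({"a": 1.0, "b": 0.0}, taxonomy=tax),
    )


class TestRunCounterfactual:
    def test_two_method_hand_arithmetic(self):
        # A = 1/0.5 + 1/0.1 = 12; D* = 12*0.5 = 6; averted 4; NNT 100/4 = 25
        res = ea.run_counterfactual(_two_method_scenario())
        assert res.total_acts == pytest.approx(12.0)
        assert res.counterfactual_total_deaths == pytest.approx(6.0)
        assert res.deaths_averted == pytest.approx(4.0)
        assert res.nnt == pytest.approx(25.0)

    def test_connecticut_headline(self, ct_scenario):
        res = ea.run_counterfactual(ct_scenario)
        assert round(res.counterfactual_total_deaths) == 55
        assert round(res.deaths_averted) == 34
        assert res.nnt == pytest.approx(762 / res.deaths_averted)

    def test_identity_counterfactual_changes_nothing(self, ct_scenario):
        acts = ea.estimate_acts(ct_scenario.deaths, ct_scenario.cfr)
        q = ea.factual_act_distribution(acts)
        res = ea.run_counterfactual(
            ea.Scenario(762, ct_scenario.deaths, ct_scenario.cfr, q)
        )
        assert res.counterfactual_total_deaths == pytest.approx(21.0, abs=1e-9)
        assert res.deaths_averted == pytest.approx(0.0, abs=1e-9)
        assert res.nnt is None

    def test_act_conservation(self, ct_scenario):
        res = ea.run_counterfactual(ct_scenario)
        assert sum(res.counterfactual_acts.values()) == pytest.approx(
            res.total_acts, rel=1e-9
        )

    def test_reciprocity_nnt_times_rd(self, ct_scenario):
        res = ea.run_counterfactual(ct_scenario)
        assert res.nnt * res.risk_difference == pytest.approx(1.0, rel=1e-9)

    def test_published_rounding_mode_redistributes_integer_total(self, ct_scenario):
        res = ea.run_counterfactual(ct_scenario, round_total_acts=True)
        assert sum(res.counterfactual_acts.values()) == pytest.approx(187.0, rel=1e-12)
        assert res.total_acts == pytest.approx(187.2973, abs=1e-4)  # reported unrounded

    def test_n_subjects_below_death_total_rejected(self, ct_scenario):
        with pytest.raises(ea.ValidationError):
            ea.Scenario(20, ct_scenario.deaths, ct_scenario.cfr, ct_scenario.counterfactual)


class TestNNTFromTotals:
    def test_historical_comparison_arithmetic(self):
        # 1 / [(93 - 21) / 762]
        s = ea.nnt_from_totals(93, 21, 762)
        assert s.nnt == pytest.approx(10.583, abs=1e-3)
        assert 100 * s.risk_difference == pytest.approx(9.449, abs=1e-3)

    def test_updated_totals(self):
        assert ea.nnt_from_totals(55.1, 21, 762).nnt == pytest.approx(22.35, abs=0.01)

    def test_no_excess_deaths_undefined(self):
        s = ea.nnt_from_totals(21, 21, 762)
        assert s.risk_difference == 0.0
        assert s.nnt is None

    def test_protective_direction_keeps_signed_rd(self):
        s = ea.nnt_from_totals(10, 21, 762)
        assert s.risk_difference < 0
        assert s.nnt is None


class TestSwansonCounterfactual:
    def test_seventy_percent_construction(self, ct_deaths, male_cfr):
        acts = ea.estimate_acts(ct_deaths, male_cfr)
        q = ea.swanson_counterfactual(acts, 0.70)
        assert q["firearm"] == 0.70
        # nonfirearm acts total = 187.2973 - 6.6372 = 180.6601
        assert q["poisoning_drugs"] == pytest.approx(0.3 * 80.0 / 180.6601, abs=1e-5)
        assert sum(q.proportions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_boundary_point_mass(self, ct_deaths, male_cfr):
        acts = ea.estimate_acts(ct_deaths, male_cfr)
        q = ea.swanson_counterfactual(acts, 1.0)
        assert q["firearm"] == 1.0
        assert all(q[m] == 0.0 for m in DEFAULT_METHODS if m != "firearm")

    def test_factual_share_reproduces_factual_distribution(self, ct_deaths, male_cfr):
        acts = ea.estimate_acts(ct_deaths, male_cfr)
        factual = ea.factual_act_distribution(acts)
        q = ea.swanson_counterfactual(acts, factual["firearm"])
        for m in DEFAULT_METHODS:
            assert q[m] == pytest.approx(factual[m], abs=1e-12)

    def test_zero_nonfirearm_acts_degenerate(self):
        acts = ea.ActEstimate({m: 0.0 for m in DEFAULT_METHODS} | {"firearm": 5.0})
        with pytest.raises(ea.DegenerateDistributionError):
            ea.swanson_counterfactual(acts, 0.5)


class TestSweep:
    def test_nnt_strictly_decreasing_in_firearm_fraction(self, ct_scenario):
        # firearm CFR exceeds every nonfirearm CFR in the male table
        grid = np.round(np.arange(0.1, 0.91, 0.05), 3)
        df = ea.sweep_firearm_fraction(ct_scenario, grid)
        nnt = df["nnt"].dropna().to_numpy()
        assert (np.diff(nnt) < 0).all()

    def test_closed_form_agreement(self, ct_scenario):
        # D*(f) = A * (f * cfr_F + (1 - f) * cbar_NF), cbar_NF acts-weighted
        acts = ea.estimate_acts(ct_scenario.deaths, ct_scenario.cfr)
        a = acts.as_series()
        p = ct_scenario.cfr.as_series()
        nf = [m for m in DEFAULT_METHODS if m != "firearm"]
        cbar_nf = (a[nf] * p[nf]).sum() / a[nf].sum()
        df = ea.sweep_firearm_fraction(ct_scenario, [0.2, 0.5, 0.8])
        for _, row in df.iterrows():
            f = row["fraction"]
            expected = acts.total_acts * (f * p["firearm"] + (1 - f) * cbar_nf)
            assert row["counterfactual_deaths"] == pytest.approx(expected, rel=1e-9)

    def test_fraction_at_factual_share_averts_nothing(self, ct_scenario):
        acts = ea.estimate_acts(ct_scenario.deaths, ct_scenario.cfr)
        share = ea.factual_act_distribution(acts)["firearm"]
        df = ea.sweep_firearm_fraction(ct_scenario, [share])
        assert df.loc[0, "deaths_averted"] == pytest.approx(0.0, abs=1e-9)
        assert math.isnan(df.loc[0, "nnt"])

    def test_empty_grid_rejected(self, ct_scenario):
        with pytest.raises(ea.ValidationError):
            ea.sweep_firearm_fraction(ct_scenario, [])


@st.composite
def small_scenarios(draw):
    k = draw(st.integers(min_value=2, max_value=4))
    tax = ea.MethodTaxonomy(tuple(f"m{i}" for i in range(k)))
    deaths = {m: draw(st.integers(min_value=0, max_value=5)) for m in tax}
    if sum(deaths.values()) == 0:
        deaths[tax.methods[0]] = 1
    cfr = {m: draw(st.floats(min_value=0.05, max_value=1.0)) for m in tax}
    weights = {m: draw(st.floats(min_value=0.01, max_value=1.0)) for m in tax}
    q = ea.normalize_distribution(weights, taxonomy=tax)
    n = sum(deaths.values()) + draw(st.integers(min_value=1, max_value=500))
    return ea.Scenario(
        n, ea.DeathTally(deaths, taxonomy=tax), ea.CFRTable(cfr, taxonomy=tax), q
    )


@given(scenario=small_scenarios())
def test_brute_force_oracle_equivalence(scenario):
    """Literal per-method loop (written independently of the engine) agrees."""
    total_acts = 0.0
    for m in scenario.deaths.taxonomy:
        if scenario.deaths[m] > 0:
            total_acts += scenario.deaths[m] / scenario.cfr[m]
    cf_deaths = 0.0
    for m in scenario.deaths.taxonomy:
        cf_deaths += total_acts * scenario.counterfactual[m] * scenario.cfr[m]
    averted = cf_deaths - scenario.deaths.total

    res = ea.run_counterfactual(scenario)
    assert res.total_acts == pytest.approx(total_acts, rel=1e-12)
    assert res.counterfactual_total_deaths == pytest.approx(cf_deaths, rel=1e-12)
    assert res.deaths_averted == pytest.approx(averted, rel=1e-9, abs=1e-9)
    if averted > 0:
        assert res.nnt == pytest.approx(scenario.n_subjects / averted, rel=1e-12)
    else:
        assert res.nnt is None
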