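"""Requirement simulation, demand-unit conversion, deposition rate, SGR."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crabgem import (
    LiteratureDemand,
    SGRParams,
    SyntheticSpec,
    deposition_rate,
    fba,
    growth_under_feed,
    literature_to_mmol,
    make_toy_gem,
    sgr,
    simulate_requirements,
)


class TestLiteratureConversion:
    @pytest.mark.parametrize("value,unit,mw,expected", [
        # amino-acid feed contents, percent of feed over free-acid mass
        (3.62, "percent_of_feed", 174.20, 0.2078),
        (2.34, "percent_of_feed", 146.19, 0.1601),
        (1.504, "percent_of_feed", 117.15, 0.1284),
        # fatty acids
        (2.79, "percent_of_feed", 280.45, 0.0995),
        (0.53, "percent_of_feed", 328.49, 0.0161),
        # minerals via the measured carrier form
        (2.9, "percent_of_feed", 100.09, 0.2897),
        (3.76, "g_per_kg", 288.50, 0.0130),
        (20.0, "mg_per_kg", 65.38, 0.0003),
    ])
    def test_feed_contents_to_mmol(self, value, unit, mw, expected):
        demand = LiteratureDemand("n", value, unit, mw)
        assert literature_to_mmol(demand) == pytest.approx(expected, abs=5e-5)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unknown unit"):
            LiteratureDemand("n", 1.0, "spoonfuls", 100.0)

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0.001, 50), st.floats(10, 500), st.floats(0.5, 4))
    def test_linear_in_value_inverse_in_mass(self, value, mw, k):
        base = literature_to_mmol(
            LiteratureDemand("n", value, "percent_of_feed", mw))
        assert literature_to_mmol(
            LiteratureDemand("n", k * value, "percent_of_feed", mw)) == \
            pytest.approx(k * base, rel=1e-9)
        assert literature_to_mmol(
            LiteratureDemand("n", value, "percent_of_feed", k * mw)) == \
            pytest.approx(base / k, rel=1e-9)


class TestDepositionRate:
    @pytest.mark.parametrize("simulated,literature,percent", [
        (0.0664, 0.1601, 41),
        (0.0071, 0.0089, 80),
    ])
    def test_printed_percentages(self, simulated, literature, percent):
        assert round(deposition_rate(simulated, literature) * 100) == percent

    def test_equal_values_give_unity(self):
        assert deposition_rate(0.5, 0.5) == pytest.approx(1.0)

    def test_zero_literature_demand_undefined(self):
        with pytest.raises(ValueError):
            deposition_rate(0.1, 0.0)


class TestSimulateRequirements:
    def test_requirement_equals_biomass_coefficient(self, toy_gem):
        """A nutrient consumed only by biomass must be absorbed at exactly
        coefficient × rate (conservation)."""
        model, truth = toy_gem
        rows = {r.nutrient: r for r in simulate_requirements(
            model, biomass_rate=1.0, parsimonious=True)}
        for mid in truth.essential_ids:
            ex = f"EX_{mid[:-3]}"
            assert rows[ex].simulated_mmol == pytest.approx(
                truth.biomass_coefficients[mid], abs=1e-8)

    def test_closed_synthesizable_import_requirement_zero(self, toy_gem):
        model, truth = toy_gem
        rows = {r.nutrient: r for r in simulate_requirements(
            model, biomass_rate=1.0, parsimonious=True)}
        for mid in truth.synthesizable_ids:
            ex = f"EX_{mid[:-3]}"
            assert rows[ex].simulated_mmol == pytest.approx(0.0, abs=1e-8)
            assert not rows[ex].accumulated

    def test_internal_overproduction_reported_negative(self, toy_gem):
        """A precursor made faster than biomass consumes it is exported:
        negative requirement flagged as accumulation."""
        model, truth = toy_gem
        syn = truth.synthesizable_ids[0]
        rid = [r for r in model.reactions if r.startswith("SYN")][0]
        model.reactions[rid].lower_bound = 3.0  # force overproduction
        rows = {r.nutrient: r for r in simulate_requirements(
            model, biomass_rate=1.0, parsimonious=True)}
        ex = f"EX_{syn[:-3]}"
        assert rows[ex].simulated_mmol < 0
        assert rows[ex].accumulated

    def test_deposition_attached_when_demand_given(self, toy_gem):
        model, truth = toy_gem
        mid = truth.essential_ids[0]
        ex = f"EX_{mid[:-3]}"
        demands = [LiteratureDemand(ex, 2.0, "percent_of_feed", 120.0)]
        rows = {r.nutrient: r for r in simulate_requirements(
            model, biomass_rate=1.0, parsimonious=True, demands=demands)}
        lit = literature_to_mmol(demands[0])
        assert rows[ex].deposition_rate == pytest.approx(
            rows[ex].simulated_mmol / lit)

    def test_infeasible_rate_raises_helpfully(self, toy_gem):
        model, truth = toy_gem
        with pytest.raises(Exception, match="precursor"):
            simulate_requirements(model, biomass_rate=1e6)


class TestSGR:
    def test_zero_growth_is_zero(self):
        assert sgr(SGRParams(x=0.0)) == (0.0, 0.0)

    def test_printed_simulation_range(self):
        """x = 0.1203 gDW/d with the defaults gives ≈ 0.74%–1.24%/d."""
        lo, hi = sgr(SGRParams(x=0.1203))
        assert lo == pytest.approx(0.7429, abs=1e-4)
        assert hi == pytest.approx(1.2351, abs=1e-4)

    def test_formula_matches_direct_evaluation(self):
        lo, hi = sgr(SGRParams(x=0.2))
        expect_lo = (math.log(8.41 + 0.2523 * 0.2 / 0.484) - math.log(8.41)) * 100
        expect_hi = (math.log(8.41 + 0.4205 * 0.2 / 0.484) - math.log(8.41)) * 100
        assert lo == pytest.approx(expect_lo, rel=1e-12)
        assert hi == pytest.approx(expect_hi, rel=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0.001, 5.0))
    def test_concave_increasing_in_x(self, x):
        lo1, hi1 = sgr(SGRParams(x=x))
        lo2, hi2 = sgr(SGRParams(x=2 * x))
        assert 0 < lo1 <= hi1
        assert lo2 > lo1 and hi2 > hi1
        assert lo2 < 2 * lo1 and hi2 < 2 * hi1  # concavity of ln

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SGRParams(water_fraction=1.2)
        with pytest.raises(ValueError):
            SGRParams(feed_fraction_min=0.05, feed_fraction_max=0.03)


class TestGrowthUnderFeed:
    def test_limiting_nutrient_caps_growth(self, toy_gem):
        """Liebig's barrel: biomass = min over nutrients of supply/need."""
        model, truth = toy_gem
        mid = truth.essential_ids[0]
        ex = f"EX_{mid[:-3]}"
        demands = [LiteratureDemand(ex, 1.0, "g_per_kg", 100.0)]  # 0.01 mmol
        result = growth_under_feed(model, demands)
        supply = literature_to_mmol(demands[0])
        expected = supply / truth.biomass_coefficients[mid]
        assert result.biomass_rate == pytest.approx(expected, rel=1e-6)

    def test_doubling_limiting_supply_doubles_growth(self, toy_gem):
        model, truth = toy_gem
        mid = truth.essential_ids[0]
        ex = f"EX_{mid[:-3]}"
        one = growth_under_feed(
            model, [LiteratureDemand(ex, 1.0, "g_per_kg", 100.0)])
        two = growth_under_feed(
            model, [LiteratureDemand(ex, 2.0, "g_per_kg", 100.0)])
        assert two.biomass_rate == pytest.approx(2 * one.biomass_rate, rel=1e-6)

    def test_ample_supply_recovers_unconstrained_optimum(self, toy_gem):
        model, truth = toy_gem
        demands = [
            LiteratureDemand(f"EX_{mid[:-3]}", 50.0, "percent_of_feed", 100.0)
            for mid in truth.essential_ids
        ]
        result = growth_under_feed(model, demands)
        assert result.biomass_rate == pytest.approx(
            fba(model).objective_value, rel=1e-6)

    def test_unabsorbed_surplus_accounted(self, toy_gem):
        model, truth = toy_gem
        mid = truth.essential_ids[0]
        ex = f"EX_{mid[:-3]}"
        demands = [LiteratureDemand(ex, 10.0, "percent_of_feed", 100.0)]
        result = growth_under_feed(model, demands)
        assert result.unabsorbed[ex] == pytest.approx(
            result.offered[ex] - result.absorbed[ex])
        assert result.unabsorbed[ex] >= -1e-9
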