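import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate

from eacrisk import (
    BEStratum,
    FactorLevel,
    IndividualProfile,
    RatePolynomial,
    RiskFactor,
    RiskFactorSet,
    UnsupportedStratumError,
    ValidationError,
    absolute_risk,
    baseline_hazard,
    bmi,
    comparator_mortality,
    delta_ci,
    format_risk,
    individual_rr,
    mean_population_rr,
)

from conftest import constant_poly, one_factor_set, two_level_factor


def two_factor_set(rr1=3.0, rr2=3.0, p1=0.5, p2=0.5):
    return RiskFactorSet(
        BEStratum.UNKNOWN_OR_NEGATIVE,
        (
            two_level_factor("f1", rr1, p1),
            two_level_factor("f2", rr2, p2),
        ),
    )


def profile(selections, age=60, sex="male", race="white"):
    return IndividualProfile(age=age, sex=sex, race=race, selections=selections)


class TestPopulationRR:
    def test_all_unit_rr_gives_one(self):
        fs = one_factor_set(two_level_factor(rr=1.0, ci=(1.0, 1.0)))
        assert mean_population_rr(fs) == pytest.approx(1.0)

    def test_single_factor_weighted_mean(self):
        fs = one_factor_set(two_level_factor(rr=3.0, prevalence_exposed=0.5))
        assert mean_population_rr(fs) == pytest.approx(2.0)

    def test_independent_factors_multiply(self):
        assert mean_population_rr(two_factor_set()) == pytest.approx(4.0)

    def test_baseline_hazard_is_incidence_over_mean_rr(self):
        fs = one_factor_set(two_level_factor(rr=3.0, prevalence_exposed=0.5))
        assert baseline_hazard(1e-4, fs) == pytest.approx(5e-5)
        # algebraic identity
        assert baseline_hazard(1e-4, fs) * mean_population_rr(fs) == pytest.approx(1e-4)

    def test_all_reference_set_leaves_incidence_unchanged(self):
        fs = one_factor_set(two_level_factor(rr=1.0, ci=(1.0, 1.0)))
        assert baseline_hazard(2e-4, fs) == pytest.approx(2e-4)


class TestIndividualRR:
    def test_reference_selections_give_one(self):
        fs = two_factor_set()
        assert individual_rr(profile({"f1": "ref", "f2": "ref"}), fs) == 1.0

    def test_products(self):
        fs = two_factor_set(rr1=2.0, rr2=3.0)
        assert individual_rr(profile({"f1": "exposed", "f2": "exposed"}), fs) == pytest.approx(6.0)

    def test_protective_levels_divide(self):
        fs = two_factor_set(rr1=6.0, rr2=0.5)
        assert individual_rr(profile({"f1": "exposed", "f2": "exposed"}), fs) == pytest.approx(3.0)

    def test_missing_selection_names_factor(self):
        fs = two_factor_set()
        with pytest.raises(ValidationError, match="f2"):
            individual_rr(profile({"f1": "ref"}), fs)


def closed_form_constant(h, m, years=10):
    """Constant-hazard competing-risks cumulative incidence (independent oracle)."""
    if h + m == 0:
        return 0.0
    return h / (h + m) * (1.0 - math.exp(-(h + m) * years))


class TestAbsoluteRisk:
    def test_zero_incidence_gives_zero(self):
        fs = one_factor_set(two_level_factor())
        p = profile({"exposure": "exposed"})
        zero = RatePolynomial((-800.0, 0.0, 0.0, 0.0), 40, 89)  # underflows to zero rate
        assert absolute_risk(p, fs, zero, constant_poly(0.02)) == pytest.approx(0.0, abs=1e-300)

    def test_constant_hazard_closed_form(self):
        # baseline 0.001 x RR 2 against mortality 0.02 over 10 years
        fs = one_factor_set(two_level_factor(rr=2.0, prevalence_exposed=0.0))
        p = profile({"exposure": "exposed"})
        ar = absolute_risk(p, fs, constant_poly(0.001), constant_poly(0.02))
        assert ar == pytest.approx(0.002 / 0.022 * (1 - math.exp(-0.22)), rel=1e-12)
        assert ar == pytest.approx(0.017953, abs=5e-7)

    def test_no_competing_mortality_limit(self):
        fs = one_factor_set(two_level_factor(rr=1.0, ci=(1.0, 1.0)))
        p = profile({"exposure": "exposed"})
        tiny = RatePolynomial((-800.0, 0.0, 0.0, 0.0), 40, 89)
        ar = absolute_risk(p, fs, constant_poly(0.003), tiny)
        assert ar == pytest.approx(1 - math.exp(-0.03), rel=1e-9)

    def test_quadrature_oracle_on_age_varying_hazards(self):
        # independent oracle: numerically integrate h(t) S(t) for the
        # piecewise-constant annual hazards the engine uses
        fs = one_factor_set(two_level_factor(rr=2.0, prevalence_exposed=0.25))
        p = profile({"exposure": "exposed"})
        inc = RatePolynomial((-14.0, 0.06, 0.0, 0.0), 40, 89)
        mort = RatePolynomial((-9.0, 0.08, 0.0, 0.0), 40, 89)
        mean_rr = mean_population_rr(fs)

        def h_step(t):
            a = 60 + math.floor(t) + 0.5
            return math.exp(-14.0 + 0.06 * a) / mean_rr * 2.0

        def m_step(t):
            a = 60 + math.floor(t) + 0.5
            return math.exp(-9.0 + 0.08 * a)

        def integrand(t):
            cum = 0.0
            # integrate piecewise-constant hazards up to t
            for k in range(int(math.floor(t))):
                cum += h_step(k) + m_step(k)
            frac = t - math.floor(t)
            cum += (h_step(t) + m_step(t)) * frac
            return h_step(t) * math.exp(-cum)

        oracle = sum(
            integrate.quad(integrand, k, k + 1, limit=200)[0] for k in range(10)
        )
        ar = absolute_risk(p, fs, inc, mort)
        assert ar == pytest.approx(oracle, rel=1e-8)

    def test_bounded_by_risk_without_competing_mortality(self):
        fs = one_factor_set(two_level_factor(rr=4.0, prevalence_exposed=0.3))
        p = profile({"exposure": "exposed"})
        inc = RatePolynomial((-11.0, 0.05, 0.0, 0.0), 40, 89)
        mort = constant_poly(0.03)
        mean_rr = mean_population_rr(fs)
        hs = [
            math.exp(-11.0 + 0.05 * (60 + t + 0.5)) / mean_rr * 4.0 for t in range(10)
        ]
        bound = 1 - math.exp(-sum(hs))
        ar = absolute_risk(p, fs, inc, mort)
        assert ar < bound
        tiny = RatePolynomial((-800.0, 0.0, 0.0, 0.0), 40, 89)
        assert absolute_risk(p, fs, inc, tiny) == pytest.approx(bound, rel=1e-12)

    def test_small_hazard_limit_is_hazard_sum(self):
        fs = one_factor_set(two_level_factor(rr=1.0, ci=(1.0, 1.0)))
        p = profile({"exposure": "exposed"})
        ar = absolute_risk(p, fs, constant_poly(1e-6), constant_poly(5e-6))
        assert ar == pytest.approx(10 * 1e-6, rel=1e-3)

    @given(st.floats(min_value=1.0, max_value=20.0))
    def test_monotone_in_selected_rr(self, rr):
        base = one_factor_set(two_level_factor(rr=rr, prevalence_exposed=0.2))
        bigger = one_factor_set(two_level_factor(rr=rr * 1.5, prevalence_exposed=0.2))
        p = profile({"exposure": "exposed"})
        inc, mort = constant_poly(1e-4), constant_poly(0.02)
        assert absolute_risk(p, bigger, inc, mort) >= absolute_risk(p, base, inc, mort)


class TestDeltaCI:
    def test_zero_se_collapses_to_point(self):
        fs = one_factor_set(two_level_factor(rr=2.0, ci=(2.0, 2.0)))
        p = profile({"exposure": "exposed"})
        ar = absolute_risk(p, fs, constant_poly(1e-4), constant_poly(0.02))
        lo, hi = delta_ci(p, fs, constant_poly(1e-4), constant_poly(0.02))
        assert lo == pytest.approx(ar)
        assert hi == pytest.approx(ar)

    def test_brackets_point_estimate(self):
        fs = one_factor_set(two_level_factor(rr=2.5, prevalence_exposed=0.3, ci=(1.8, 3.47)))
        p = profile({"exposure": "exposed"})
        inc, mort = constant_poly(1e-4), constant_poly(0.02)
        ar = absolute_risk(p, fs, inc, mort)
        lo, hi = delta_ci(p, fs, inc, mort)
        assert 0 <= lo <= ar <= hi <= 1

    def test_matches_parametric_bootstrap_width(self):
        # Monte-Carlo oracle: draw log-normal RRs, recompute the risk by the
        # constant-hazard closed form, compare CI widths
        rr, lo_ci, hi_ci, p_exp = 2.5, 1.8, 3.47, 0.3
        fs = one_factor_set(two_level_factor(rr=rr, prevalence_exposed=p_exp, ci=(lo_ci, hi_ci)))
        p = profile({"exposure": "exposed"})
        inc_rate, mort_rate = 1e-4, 0.02
        inc, mort = constant_poly(inc_rate), constant_poly(mort_rate)
        lo, hi = delta_ci(p, fs, inc, mort)
        se = (math.log(hi_ci) - math.log(lo_ci)) / (2 * 1.959963984540054)
        rng = np.random.default_rng(20240613)
        draws = np.exp(rng.normal(math.log(rr), se, size=10_000))
        h = inc_rate / (1 - p_exp + p_exp * draws) * draws
        ars = h / (h + mort_rate) * (1 - np.exp(-10 * (h + mort_rate)))
        blo, bhi = np.percentile(ars, [2.5, 97.5])
        assert (hi - lo) == pytest.approx(bhi - blo, rel=0.10)

    def test_rare_disease_single_factor_ci_ratio(self):
        # with reference prevalence ~1 the PAR channel vanishes and
        # log AR is linear in log RR: CI ratio ~ ci_high / rr
        rr, hi_ci = 3.0, 4.2
        fs = one_factor_set(
            two_level_factor(rr=rr, prevalence_exposed=1e-6, ci=(rr**2 / hi_ci, hi_ci))
        )
        p = profile({"exposure": "exposed"})
        inc, mort = constant_poly(1e-5), constant_poly(0.01)
        ar = absolute_risk(p, fs, inc, mort)
        assert ar < 0.01
        lo, hi = delta_ci(p, fs, inc, mort)
        assert hi / ar == pytest.approx(hi_ci / rr, rel=0.05)

    def test_nonfinite_ci_rejected(self):
        f = two_level_factor(rr=2.0, ci=(1.5, math.inf))
        fs = one_factor_set(f)
        p = profile({"exposure": "exposed"})
        with pytest.raises(ValidationError, match="non-finite"):
            delta_ci(p, fs, constant_poly(1e-4), constant_poly(0.02))


class TestFormatRisk:
    @pytest.mark.parametrize(
        "prob10, per_1000, one_in_n",
        [
            (0.0057, 5.7, 175),
            (0.034, 34.0, 29),
            (1.0, 1000.0, 1),
            (0.5, 500.0, 2),
        ],
    )
    def test_display_forms(self, prob10, per_1000, one_in_n):
        d = format_risk(prob10)
        assert d.per_1000 == per_1000
        assert d.one_in_n == one_in_n

    def test_zero_probability_sentinel(self):
        d = format_risk(0.0)
        assert d.one_in_n is None
        assert d.category == "none expected"

    @pytest.mark.parametrize(
        "per_1000, category",
        [(0.3, "very low"), (1.0, "low"), (5.7, "moderate"), (10.0, "high"), (34.0, "very high")],
    )
    def test_log_scale_categories(self, per_1000, category):
        assert format_risk(per_1000 / 1000).category == category

    @given(st.floats(min_value=1e-6, max_value=1.0))
    def test_one_in_n_consistent_with_per_1000(self, prob10):
        d = format_risk(prob10)
        if d.per_1000 > 0:
            assert d.one_in_n == round(1000.0 / d.per_1000)


class TestComparatorMortality:
    def test_zero_cause_hazard(self):
        tiny = RatePolynomial((-800.0, 0.0, 0.0, 0.0), 40, 89)
        out = comparator_mortality(60, "male", "white", {"x": tiny}, constant_poly(0.02))
        assert out["x"] == pytest.approx(0.0, abs=1e-300)

    def test_constant_hazards_closed_form(self):
        cause = constant_poly(0.005)
        total = constant_poly(0.02)
        out = comparator_mortality(60, "male", "white", {"c": cause}, total)
        assert out["c"] == pytest.approx(closed_form_constant(0.005, 0.015), rel=1e-12)

    def test_exhaustive_partition_sums_to_allcause_probability(self):
        # consistent inputs: cause polynomials are exact shares of all-cause
        total = RatePolynomial((-9.0, 0.08, 0.0, 0.0), 40, 89)
        shares = {"a": 0.5, "b": 0.3, "c": 0.2}
        causes = {
            name: RatePolynomial(
                (total.coefficients[0] + math.log(s),) + total.coefficients[1:], 40, 89
            )
            for name, s in shares.items()
        }
        out = comparator_mortality(65, "male", "white", causes, total)
        hs = [math.exp(-9.0 + 0.08 * (65 + t + 0.5)) for t in range(10)]
        allcause_prob = 1 - math.exp(-sum(hs))
        assert sum(out.values()) == pytest.approx(allcause_prob, abs=1e-9)


class TestBMI:
    @pytest.mark.parametrize(
        "value, category",
        [
            (17.0, "underweight"),
            (22.0, "normal"),
            (28.0, "overweight"),
            (31.0, "obese category I"),
            (36.0, "obese category II"),
            (42.0, "obese category III"),
            (25.0, "overweight"),  # left-closed boundary
        ],
    )
    def test_categories(self, value, category):
        v, cat = bmi(value, 1.0)
        assert v == pytest.approx(value)
        assert cat == category

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            bmi(0.0, 1.7)
        with pytest.raises(ValidationError):
            bmi(70.0, -1.7)


class TestCalculator:
    def test_black_female_unsupported(self, default_calculator, reference_selections):
        p = IndividualProfile(
            age=60, sex="female", race="black", selections=reference_selections
        )
        with pytest.raises(UnsupportedStratumError, match="stratum unsupported"):
            default_calculator.score(p)

    def test_be_stratum_uses_be_model_and_factors(self, default_calculator):
        fs = default_calculator.factor_sets[BEStratum.POSITIVE]
        sel = {f.name: f.reference.label for f in fs}
        p = IndividualProfile(
            age=62, sex="male", race="white", be_stratum="positive", selections=sel
        )
        est = default_calculator.score(p)
        # BE baseline incidence is 0.31%/yr: ten-year risk must exceed any
        # plausible general-population estimate
        assert est.prob10 > 0.005

    def test_score_matches_free_functions(self, default_calculator, reference_selections):
        p = IndividualProfile(age=60, sex="male", race="white", selections=reference_selections)
        est = default_calculator.score(p)
        assert est.prob10 == pytest.approx(default_calculator.prob10(p))
        assert est.relative_risk == pytest.approx(1.0)
        assert 0 <= est.ci_low <= est.prob10 <= est.ci_high <= 1
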