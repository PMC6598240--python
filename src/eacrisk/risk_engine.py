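"""Ten-year absolute risk of esophageal adenocarcinoma with competing mortality.

The absolute-risk model follows the classical attributable-risk construction
for cancer risk projection:

1. the *baseline* hazard (hazard at the lowest risk level of every factor) is
   population incidence divided by the population-mean relative risk
   ``E[RR] = prod_f sum_l prevalence_{f,l} RR_{f,l}`` (equivalently,
   ``1 - PAR = 1 / E[RR]``);
2. an individual's relative risk is the product of the RRs of their selected
   factor levels (multiplicative, independent factors);
3. baseline hazard x individual RR and the all-cause mortality hazard are
   combined over the 10-year horizon in annual steps, each step treated as a
   piecewise-constant competing-risks interval:

   ``AR = sum_t S_t * h_t / (h_t + m_t) * (1 - exp(-(h_t + m_t)))``

   with ``S_t = exp(-sum_{u<t} (h_u + m_u))`` and hazards evaluated at
   mid-interval age.

Confidence intervals propagate the published RR uncertainties through both
channels (the individual RR product and the population-mean RR behind the
baseline hazard) by the delta method on the log-risk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .parameters import (
    BEStratum,
    FactorLevel,
    Race,
    RiskFactor,
    RiskFactorSet,
    Sex,
    UnsupportedStratumError,
    ValidationError,
    load_rate_table,
    load_risk_factors,
)
from .rates import (
    BEIncidenceModel,
    RatePolynomial,
    be_incidence,
    evaluate_rate,
    fit_rate_polynomial,
)

__all__ = [
    "IndividualProfile",
    "RiskEstimate",
    "Calculator",
    "mean_population_rr",
    "baseline_hazard",
    "individual_rr",
    "absolute_risk",
    "delta_ci",
    "format_risk",
    "comparator_mortality",
    "bmi",
    "RISK_CATEGORIES",
]

HORIZON_YEARS = 10

#: thermometer bins on the per-1000 ten-year risk scale (log-spaced)
RISK_CATEGORIES = (
    (0.5, "very low"),
    (2.0, "low"),
    (8.0, "moderate"),
    (32.0, "high"),
    (math.inf, "very high"),
)


@dataclass(frozen=True)
class IndividualProfile:
    """Demographics plus one selected level per active risk factor.

    ``selections`` maps factor name to level label for every factor in the
    active stratum's factor set (BE-specific predictors such as segment
    length and dysplasia are ordinary selections in the positive stratum).
    """

    age: int
    sex: Sex
    race: Race
    be_stratum: BEStratum = BEStratum.UNKNOWN_OR_NEGATIVE
    selections: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "race", Race(self.race))
        object.__setattr__(self, "be_stratum", BEStratum(self.be_stratum))
        object.__setattr__(self, "selections", dict(self.selections))
        if not 40 <= int(self.age) <= 89:
            raise ValidationError(f"age must be an integer in [40, 89], got {self.age}")


@dataclass(frozen=True)
class RiskEstimate:
    """A scored profile: 10-year probability with CI and display forms."""

    prob10: float
    ci_low: float
    ci_high: float
    per_1000: float
    one_in_n: int | None
    category: str
    relative_risk: float
    comparator_mortality: Mapping[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "prob10": self.prob10,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "per_1000": self.per_1000,
            "one_in_n": self.one_in_n,
            "category": self.category,
            "relative_risk": self.relative_risk,
            "comparator_mortality": dict(self.comparator_mortality),
        }


# ---------------------------------------------------------------------------
# Relative-risk algebra
# ---------------------------------------------------------------------------

def mean_population_rr(factors: RiskFactorSet) -> float:
    """Population-mean relative risk under independent multiplicative factors.

    ``prod_f sum_l prevalence * rr``; its reciprocal is ``1 - PAR``, the share
    of population incidence a lowest-risk individual experiences.
    """
    out = 1.0
    for f in factors:
        out *= sum(lv.prevalence * lv.rr for lv in f.levels)
    return out


def baseline_hazard(incidence: float, factors: RiskFactorSet) -> float:
    """Hazard for a person at the reference level of every factor."""
    if incidence < 0:
        raise ValidationError("incidence must be >= 0")
    return incidence / mean_population_rr(factors)


def individual_rr(profile: IndividualProfile, factors: RiskFactorSet) -> float:
    """Product of the selected levels' relative risks."""
    out = 1.0
    for f in factors:
        try:
            label = profile.selections[f.name]
        except KeyError:
            raise ValidationError(f"profile is missing a selection for factor {f.name!r}") from None
        out *= f.level(label).rr
    return out


# ---------------------------------------------------------------------------
# Absolute risk
# ---------------------------------------------------------------------------

def _incidence_at(
    model: RatePolynomial | BEIncidenceModel, age: float, sex: Sex, race: Race
) -> float:
    if isinstance(model, BEIncidenceModel):
        return be_incidence(model, age, sex, race)
    return evaluate_rate(model, age)


def _risk_from_hazards(h: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Cause-specific cumulative incidence for piecewise-constant annual hazards.

    ``h`` and ``m`` have shape (..., horizon); returns shape (...,).
    """
    tot = h + m
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, h / np.where(tot > 0, tot, 1.0), 0.0)
    step = frac * (1.0 - np.exp(-tot))
    cum = np.cumsum(tot, axis=-1)
    surv = np.exp(-(cum - tot))  # survival to the start of each interval
    return np.sum(step * surv, axis=-1)


def _annual_hazards(
    profile: IndividualProfile,
    factors: RiskFactorSet,
    incidence_model: RatePolynomial | BEIncidenceModel,
    mortality: RatePolynomial,
    horizon: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Mid-interval population incidence and competing mortality for each year."""
    ages = profile.age + np.arange(horizon) + 0.5
    inc = np.array([_incidence_at(incidence_model, a, profile.sex, profile.race) for a in ages])
    mort = np.array([evaluate_rate(mortality, a) for a in ages])
    return inc, mort


def absolute_risk(
    profile: IndividualProfile,
    factors: RiskFactorSet,
    incidence_model: RatePolynomial | BEIncidenceModel,
    mortality: RatePolynomial,
    horizon: int = HORIZON_YEARS,
) -> float:
    """Absolute risk of EAC over the horizon, adjusted for competing mortality."""
    inc, mort = _annual_hazards(profile, factors, incidence_model, mortality, horizon)
    r = individual_rr(profile, factors)
    h = inc / mean_population_rr(factors) * r
    return float(_risk_from_hazards(h, mort))


def _perturbed_factor_set(
    factors: RiskFactorSet, factor_name: str, level_label: str, log_shift: float
) -> RiskFactorSet:
    """Multiply one level's RR by exp(log_shift), widening its CI bounds as needed.

    Only rr enters downstream arithmetic; ci bounds are stretched to keep the
    level's own invariant satisfied.
    """
    new_factors = []
    for f in factors:
        if f.name != factor_name:
            new_factors.append(f)
            continue
        levels = []
        for lv in f.levels:
            if lv.label == level_label:
                rr = lv.rr * math.exp(log_shift)
                levels.append(
                    FactorLevel(
                        label=lv.label,
                        rr=rr,
                        ci_low=min(lv.ci_low, rr),
                        ci_high=max(lv.ci_high, rr),
                        prevalence=lv.prevalence,
                    )
                )
            else:
                levels.append(lv)
        new_factors.append(RiskFactor(f.name, tuple(levels), f.reference_level))
    return RiskFactorSet(factors.be_stratum, tuple(new_factors))


_GRAD_STEP = 1e-4  # central-difference step on the log-RR scale


def delta_ci(
    profile: IndividualProfile,
    factors: RiskFactorSet,
    incidence_model: RatePolynomial | BEIncidenceModel,
    mortality: RatePolynomial,
    level: float = 0.95,
    horizon: int = HORIZON_YEARS,
) -> tuple[float, float]:
    """Delta-method confidence interval for the absolute risk.

    The standard error of each selected level's log RR is read off its
    published 95% CI.  The gradient of log(risk) with respect to each
    factor's log RR is computed by central finite differences, perturbing the
    factor inside both the individual RR product and the population-mean RR
    (so uncertainty flows through the attributable-fraction baseline as well).
    Factor estimates are treated as independent; the CI is log-normal around
    the point estimate.
    """
    z95 = stats.norm.ppf(0.975)  # published CIs are 95% whatever `level` is requested
    z = stats.norm.ppf(0.5 + level / 2.0)
    ar = absolute_risk(profile, factors, incidence_model, mortality, horizon)
    if ar <= 0:
        return 0.0, 0.0
    var_log = 0.0
    for f in factors:
        lv = f.level(profile.selections[f.name])
        if not all(map(math.isfinite, (lv.ci_low, lv.ci_high, lv.rr))):
            raise ValidationError(f"factor {f.name!r}: non-finite CI inputs")
        se = (math.log(lv.ci_high) - math.log(lv.ci_low)) / (2.0 * z95)
        if se == 0.0:
            continue
        up = _perturbed_factor_set(factors, f.name, lv.label, _GRAD_STEP)
        dn = _perturbed_factor_set(factors, f.name, lv.label, -_GRAD_STEP)
        grad = (
            math.log(absolute_risk(profile, up, incidence_model, mortality, horizon))
            - math.log(absolute_risk(profile, dn, incidence_model, mortality, horizon))
        ) / (2.0 * _GRAD_STEP)
        var_log += (grad * se) ** 2
    half = z * math.sqrt(var_log)
    return ar * math.exp(-half), min(1.0, ar * math.exp(half))


# ---------------------------------------------------------------------------
# Display forms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskDisplay:
    per_1000: float
    one_in_n: int | None
    category: str
    filled_circles: int


def format_risk(prob10: float) -> RiskDisplay:
    """Display forms of a 10-year probability: per-1000 (1 decimal), '1 in N', category.

    A zero probability has no meaningful '1 in N'; the sentinel category
    "none expected" is returned instead.
    """
    if not 0.0 <= prob10 <= 1.0:
        raise ValidationError(f"prob10 must be in [0, 1], got {prob10}")
    per_1000 = round(1000.0 * prob10, 1)
    if prob10 == 0.0:
        return RiskDisplay(0.0, None, "none expected", 0)
    if per_1000 > 0:
        one_in_n = round(1000.0 / per_1000)
    else:  # risk below 0.05 per 1000 rounds to 0.0; fall back to the raw probability
        one_in_n = round(1.0 / prob10)
    for upper, name in RISK_CATEGORIES:
        if per_1000 < upper:
            category = name
            break
    return RiskDisplay(per_1000, int(one_in_n), category, int(round(per_1000)))


def bmi(weight_kg: float, height_m: float) -> tuple[float, str]:
    """Body-mass index and its WHO category (left-closed bins)."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValidationError("weight and height must be > 0")
    value = weight_kg / height_m**2
    bins = (
        (18.5, "underweight"),
        (25.0, "normal"),
        (30.0, "overweight"),
        (35.0, "obese category I"),
        (40.0, "obese category II"),
        (math.inf, "obese category III"),
    )
    for upper, name in bins:
        if value < upper:
            return value, name
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Comparator mortality (thermometer context)
# ---------------------------------------------------------------------------

def comparator_mortality(
    age: int,
    sex: Sex,
    race: Race,
    cause_polys: Mapping[str, RatePolynomial],
    allcause_poly: RatePolynomial,
    horizon: int = HORIZON_YEARS,
) -> dict[str, float]:
    """10-year probability of death from each cause, for display context.

    Each cause's hazard competes against mortality from all other causes
    (all-cause minus the cause itself).  These are demographic averages only:
    they are not adjusted for the individual's risk-factor selections.
    """
    ages = age + np.arange(horizon) + 0.5
    total = np.array([evaluate_rate(allcause_poly, a) for a in ages])
    out: dict[str, float] = {}
    for cause, poly in cause_polys.items():
        h = np.array([evaluate_rate(poly, a) for a in ages])
        m = np.maximum(total - h, 0.0)
        out[cause] = float(_risk_from_hazards(h, m))
    return out


# ---------------------------------------------------------------------------
# Calculator: configuration bundle + one-call scoring
# ---------------------------------------------------------------------------

@dataclass
class Calculator:
    """Everything needed to score a profile: factor sets, fitted rate models, BE model."""

    factor_sets: dict[BEStratum, RiskFactorSet]
    incidence: dict[tuple[Sex, Race], RatePolynomial]
    mortality: dict[tuple[Sex, Race], RatePolynomial]
    causes: dict[tuple[Sex, Race], dict[str, RatePolynomial]]
    be_model: BEIncidenceModel = field(default_factory=BEIncidenceModel)

    @classmethod
    def from_config_dir(cls, config_dir: str | Path) -> "Calculator":
        """Load the five parameter CSVs and fit the rate polynomials."""
        d = Path(config_dir)
        factor_sets = {
            BEStratum.UNKNOWN_OR_NEGATIVE: load_risk_factors(
                d / "risk_factors_general.csv", BEStratum.UNKNOWN_OR_NEGATIVE
            ),
            BEStratum.POSITIVE: load_risk_factors(
                d / "risk_factors_be.csv", BEStratum.POSITIVE
            ),
        }
        incidence = {
            (t.sex, t.race): fit_rate_polynomial(t)
            for t in load_rate_table(d / "rates_incidence.csv", "eac_incidence")
        }
        mortality = {
            (t.sex, t.race): fit_rate_polynomial(t)
            for t in load_rate_table(d / "rates_mortality_allcause.csv", "all_cause_mortality")
        }
        causes: dict[tuple[Sex, Race], dict[str, RatePolynomial]] = {}
        for t in load_rate_table(d / "rates_mortality_causes.csv", "cause_specific_mortality"):
            causes.setdefault((t.sex, t.race), {})[t.cause] = fit_rate_polynomial(t)
        return cls(factor_sets=factor_sets, incidence=incidence, mortality=mortality, causes=causes)

    # -- stratum plumbing ---------------------------------------------------

    def _models_for(
        self, profile: IndividualProfile
    ) -> tuple[RiskFactorSet, RatePolynomial | BEIncidenceModel, RatePolynomial]:
        key = (profile.sex, profile.race)
        factors = self.factor_sets[profile.be_stratum]
        if key not in self.mortality:
            raise UnsupportedStratumError(
                f"stratum unsupported: no mortality data for {profile.sex.value} {profile.race.value}"
            )
        if profile.be_stratum is BEStratum.POSITIVE:
            if key not in self.be_model.sex_race_multipliers:
                raise UnsupportedStratumError(
                    f"stratum unsupported: no BE incidence data for "
                    f"{profile.sex.value} {profile.race.value}"
                )
            inc: RatePolynomial | BEIncidenceModel = self.be_model
        else:
            if key not in self.incidence:
                raise UnsupportedStratumError(
                    f"stratum unsupported: no incidence data for "
                    f"{profile.sex.value} {profile.race.value}"
                )
            inc = self.incidence[key]
        return factors, inc, self.mortality[key]

    # -- scoring ------------------------------------------------------------

    def score(self, profile: IndividualProfile, ci_level: float = 0.95) -> RiskEstimate:
        """Full risk estimate for one profile, including display forms and comparators."""
        factors, inc, mort = self._models_for(profile)
        ar = absolute_risk(profile, factors, inc, mort)
        lo, hi = delta_ci(profile, factors, inc, mort, level=ci_level)
        disp = format_risk(ar)
        comp = comparator_mortality(
            profile.age,
            profile.sex,
            profile.race,
            self.causes.get((profile.sex, profile.race), {}),
            mort,
        )
        return RiskEstimate(
            prob10=ar,
            ci_low=lo,
            ci_high=hi,
            per_1000=disp.per_1000,
            one_in_n=disp.one_in_n,
            category=disp.category,
            relative_risk=individual_rr(profile, factors),
            comparator_mortality=comp,
        )

    def prob10(self, profile: IndividualProfile) -> float:
        """10-year absolute risk only (no CI/comparators); cheap path for batch scoring."""
        factors, inc, mort = self._models_for(profile)
        return absolute_risk(profile, factors, inc, mort)
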