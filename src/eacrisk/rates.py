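"""Smoothing of age-specific rates and the Barrett's-esophagus incidence sub-model.

Registry rate tables come in 5-year age groups; for use inside the risk
integration they are smoothed with a cubic polynomial in age fitted on the
log-rate scale (log keeps every evaluated rate positive).  Persons with
diagnosed BE use a separate incidence model anchored at a published annual
progression rate instead of registry incidence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import (
    RateTable,
    Race,
    Sex,
    UnsupportedStratumError,
    ValidationError,
)

__all__ = [
    "RatePolynomial",
    "BEIncidenceModel",
    "fit_rate_polynomial",
    "evaluate_rate",
    "be_incidence",
    "competing_mortality",
    "polynomials_to_frame",
    "save_polynomials",
]

logger = logging.getLogger(__name__)

#: minimum age supported by the calculator (registry tables start at 40)
MIN_AGE = 40.0


@dataclass(frozen=True)
class RatePolynomial:
    """Cubic in age on the log-rate scale: rate(a) = exp(c0 + c1 a + c2 a^2 + c3 a^3).

    ``domain`` records the age span of the data behind the fit; evaluation
    clamps ages above ``age_max`` rather than extrapolate the cubic.
    """

    coefficients: tuple[float, float, float, float]
    age_min: float
    age_max: float
    stratum: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        if len(self.coefficients) != 4:
            raise ValidationError("RatePolynomial needs exactly 4 coefficients (c0..c3)")
        if not self.age_min < self.age_max:
            raise ValidationError("invalid polynomial domain")

    def __call__(self, age: float) -> float:
        return evaluate_rate(self, age)


@dataclass(frozen=True)
class BEIncidenceModel:
    """Annual EAC incidence for persons with diagnosed Barrett's esophagus.

    Anchored at ``anchor_rate`` per person-year for white males at
    ``anchor_age`` (the midpoint of the 60-64 group, a typical age at BE
    diagnosis), scaled by ``age_factor`` per year of age, with fixed
    sex/race multipliers.  Strata absent from ``sex_race_multipliers``
    (black females in particular) are unsupported.
    """

    anchor_rate: float = 0.0031
    anchor_age: float = 62.0
    age_factor: float = 1.04
    sex_race_multipliers: Mapping[tuple[Sex, Race], float] = field(
        default_factory=lambda: {
            (Sex.MALE, Race.WHITE): 1.0,
            (Sex.FEMALE, Race.WHITE): 0.4,
            (Sex.MALE, Race.BLACK): 0.75,
        }
    )

    def __post_init__(self) -> None:
        if self.anchor_rate <= 0 or self.age_factor <= 0:
            raise ValidationError("anchor_rate and age_factor must be > 0")
        if any(m <= 0 for m in self.sex_race_multipliers.values()):
            raise ValidationError("sex/race multipliers must be > 0")


def fit_rate_polynomial(table: RateTable) -> RatePolynomial:
    """Least-squares cubic fit of log(rate) against age-group midpoints.

    The 85+ group contributes its closed-interval midpoint like any other
    row.  Zero rates (possible in sparse strata) are floored at half the
    smallest positive rate in the table before the log transform; floored
    cells are logged.  Internally the fit uses a scaled basis and converts
    back to raw-age coefficients, so exact-cubic inputs are recovered to
    high precision.
    """
    ages = np.asarray(table.midpoints(), dtype=float)
    rates = np.asarray(table.rates(), dtype=float)
    positive = rates[rates > 0]
    if positive.size == 0:
        raise ValidationError("rate table has no positive rates to fit")
    if rates.size < 4:
        raise ValidationError(f"need >= 4 age groups to fit a cubic, got {rates.size}")
    floor = 0.5 * positive.min()
    if (rates <= 0).any():
        n_zero = int((rates <= 0).sum())
        logger.warning(
            "flooring %d zero rate(s) at %.3g before log transform (%s)",
            n_zero,
            floor,
            table.outcome,
        )
        rates = np.where(rates > 0, rates, floor)
    fit = np.polynomial.Polynomial.fit(ages, np.log(rates), deg=3)
    coefs = fit.convert().coef
    coefs = np.pad(coefs, (0, 4 - coefs.size))  # degenerate fits may drop trailing terms
    return RatePolynomial(
        coefficients=tuple(coefs),
        age_min=float(table.age_min),
        age_max=float(table.age_max),
        stratum=(table.sex.value, table.race.value, table.outcome)
        + ((table.cause,) if table.cause else ()),
    )


def evaluate_rate(poly: RatePolynomial, age: float) -> float:
    """Evaluate the smoothed rate at an age (events per person-year).

    Ages above the fitted domain are clamped to its maximum; ages below 40
    are outside the calculator's supported range and raise.
    """
    if age < MIN_AGE:
        raise ValidationError(f"age {age} below supported minimum of {MIN_AGE:.0f}")
    a = min(float(age), poly.age_max)
    c0, c1, c2, c3 = poly.coefficients
    return math.exp(c0 + a * (c1 + a * (c2 + a * c3)))


def be_incidence(model: BEIncidenceModel, age: float, sex: Sex | str, race: Race | str) -> float:
    """EAC incidence for a person with diagnosed BE: anchor x age_factor^(age-anchor) x sex/race multiplier."""
    sex, race = Sex(sex), Race(race)
    if age < MIN_AGE:
        raise ValidationError(f"age {age} below supported minimum of {MIN_AGE:.0f}")
    try:
        mult = model.sex_race_multipliers[(sex, race)]
    except KeyError:
        raise UnsupportedStratumError(
            f"stratum unsupported: no BE incidence data for {sex.value} {race.value}"
        ) from None
    return model.anchor_rate * model.age_factor ** (age - model.anchor_age) * mult


def competing_mortality(poly_allcause: RatePolynomial, age: float) -> float:
    """All-cause mortality hazard at an age, used as the competing risk.

    The all-cause hazard is used unadjusted for EAC deaths, which are a
    negligible share of total mortality.
    """
    return evaluate_rate(poly_allcause, age)


# ---------------------------------------------------------------------------
# Serialization of fitted polynomials (for inspection / reproducibility)
# ---------------------------------------------------------------------------

def polynomials_to_frame(polys: list[RatePolynomial]) -> pd.DataFrame:
    rows = []
    for p in polys:
        c0, c1, c2, c3 = p.coefficients
        rows.append(
            {
                "stratum": "/".join(map(str, p.stratum)) or "unlabelled",
                "c0": c0,
                "c1": c1,
                "c2": c2,
                "c3": c3,
                "age_min": p.age_min,
                "age_max": p.age_max,
            }
        )
    return pd.DataFrame(rows)


def save_polynomials(polys: list[RatePolynomial], path: str | Path) -> None:
    polynomials_to_frame(polys).to_csv(path, index=False)
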