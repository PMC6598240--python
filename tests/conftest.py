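import math

import pytest
from hypothesis import HealthCheck, settings

from eacrisk import (
    BEStratum,
    Calculator,
    FactorLevel,
    RatePolynomial,
    RiskFactor,
    RiskFactorSet,
    default_config_dir,
)

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


def constant_poly(rate: float, age_min: float = 40.0, age_max: float = 89.0) -> RatePolynomial:
    """Polynomial evaluating to a constant rate at every age."""
    return RatePolynomial((math.log(rate), 0.0, 0.0, 0.0), age_min, age_max)


def two_level_factor(
    name: str = "exposure",
    rr: float = 2.0,
    prevalence_exposed: float = 0.4,
    ci: tuple[float, float] | None = None,
) -> RiskFactor:
    lo, hi = ci if ci is not None else (rr, rr)
    return RiskFactor(
        name=name,
        levels=(
            FactorLevel("ref", 1.0, 1.0, 1.0, 1.0 - prevalence_exposed),
            FactorLevel("exposed", rr, lo, hi, prevalence_exposed),
        ),
        reference_level=0,
    )


def one_factor_set(factor: RiskFactor) -> RiskFactorSet:
    return RiskFactorSet(BEStratum.UNKNOWN_OR_NEGATIVE, (factor,))


@pytest.fixture(scope="session")
def default_calculator() -> Calculator:
    """Calculator built from the packaged synthetic default config."""
    return Calculator.from_config_dir(default_config_dir())


@pytest.fixture()
def reference_selections(default_calculator):
    """All-reference selections for the general-population factor set."""
    fs = default_calculator.factor_sets[BEStratum.UNKNOWN_OR_NEGATIVE]
    return {f.name: f.reference.label for f in fs}
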