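"""Synthetic rate tables and case-control populations with known ground truth.

Real registry rates and consortium case-control data cannot ship with the
package; this module generates stand-ins whose generating parameters are
known exactly, so every other module can be exercised and checked offline.
Case records are drawn with per-factor independent RR tilting — the same
multiplicative, independent-factor family the risk engine assumes — so
parameter-recovery experiments test the pipeline rather than model
misspecification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discrimination import CaseControlRecord, tilted_level_probs
from .parameters import (
    AgeGroupRate,
    Race,
    RateTable,
    RiskFactorSet,
    Sex,
    ValidationError,
)

__all__ = [
    "SimulationSpec",
    "generate_rate_table",
    "generate_case_control",
    "default_reference_distribution",
    "AGE_GROUPS",
]

#: the calculator's 5-year age groups, 40 through 85+ (closed at 89)
AGE_GROUPS: tuple[tuple[int, int], ...] = tuple(
    (lo, lo + 4) for lo in range(40, 90, 5)
)


def generate_rate_table(
    shape: str,
    params: dict,
    sex: Sex | str = Sex.MALE,
    race: Race | str = Race.WHITE,
    outcome: str = "eac_incidence",
    cause: str | None = None,
) -> RateTable:
    """Build a 5-year age-group rate table from a named generator.

    Shapes: ``constant`` (params: rate), ``gompertz`` (params: a, b — rate
    a*exp(b*age)), ``cubic`` (params: c0..c3 — rate exp(cubic in age)).
    """
    mids = np.array([(lo + hi) / 2.0 for lo, hi in AGE_GROUPS])
    if shape == "constant":
        rate = float(params["rate"])
        if rate < 0:
            raise ValidationError("constant rate must be >= 0")
        rates = np.full(mids.shape, rate)
    elif shape == "gompertz":
        a, b = float(params["a"]), float(params["b"])
        if a <= 0:
            raise ValidationError("gompertz scale 'a' must be > 0")
        rates = a * np.exp(b * mids)
    elif shape == "cubic":
        c = [float(params[k]) for k in ("c0", "c1", "c2", "c3")]
        rates = np.exp(c[0] + c[1] * mids + c[2] * mids**2 + c[3] * mids**3)
    else:
        raise ValidationError(f"unknown rate shape {shape!r}")
    rows = tuple(
        AgeGroupRate(lo, hi, float(r)) for (lo, hi), r in zip(AGE_GROUPS, rates)
    )
    return RateTable(outcome=outcome, sex=Sex(sex), race=Race(race), rows=rows, cause=cause)


def default_reference_distribution() -> pd.DataFrame:
    """A plausible (age-group, sex) population distribution over ages 40-89.

    Mass declines with age roughly like the US 40+ population; used both as
    the sampling frame for synthetic controls and as the post-stratification
    reference.
    """
    rows = []
    weights = np.array([1.15, 1.1, 1.05, 1.0, 0.9, 0.75, 0.55, 0.4, 0.25, 0.15])
    for sex, sex_share in ((Sex.MALE, 0.49), (Sex.FEMALE, 0.51)):
        for (lo, hi), w in zip(AGE_GROUPS, weights):
            rows.append({"age_lo": lo, "age_hi": hi, "sex": sex.value, "proportion": w * sex_share})
    df = pd.DataFrame(rows)
    df["proportion"] /= df["proportion"].sum()
    return df


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth for a synthetic case-control study.

    The factor set's RRs play the role of odds ratios (interchangeable under
    the rare-disease assumption); its prevalences are the control level
    distribution.  ``missing_rate`` applies missing-completely-at-random
    blanking to factor selections.
    """

    n_cases: int
    n_controls: int
    factor_set: RiskFactorSet
    reference: pd.DataFrame = field(default_factory=default_reference_distribution)
    seed: int = 0
    missing_rate: float = 0.0
    race: Race = Race.WHITE

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValidationError("counts must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")


def generate_case_control(spec: SimulationSpec) -> list[CaseControlRecord]:
    """Draw a case-control population from the spec; byte-identical given the seed.

    Controls take factor levels from the prevalences; cases from the
    RR-tilted distribution, independently per factor.  Ages and sexes for
    both arms come from the reference distribution (controls in the source
    studies were frequency-matched to cases).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases + spec.n_controls
    is_case = np.concatenate(
        [np.ones(spec.n_cases, dtype=bool), np.zeros(spec.n_controls, dtype=bool)]
    )
    ref = spec.reference.reset_index(drop=True)
    cell_probs = ref["proportion"].to_numpy(dtype=float)
    cell_probs = cell_probs / cell_probs.sum()
    cells = rng.choice(len(ref), size=n, p=cell_probs)
    lo = ref["age_lo"].to_numpy()[cells]
    hi = ref["age_hi"].to_numpy()[cells]
    ages = rng.integers(lo, hi + 1)
    sexes = ref["sex"].to_numpy()[cells]

    level_draws: dict[str, np.ndarray] = {}
    level_labels: dict[str, list[str]] = {}
    for f in spec.factor_set:
        labels = [lv.label for lv in f.levels]
        p_ctrl = np.array([lv.prevalence for lv in f.levels], dtype=float)
        rrs = np.array([lv.rr for lv in f.levels], dtype=float)
        p_case = tilted_level_probs(p_ctrl, rrs)
        u = rng.random(n)
        idx = np.where(
            is_case,
            np.searchsorted(np.cumsum(p_case), u, side="right"),
            np.searchsorted(np.cumsum(p_ctrl), u, side="right"),
        )
        level_draws[f.name] = np.minimum(idx, len(labels) - 1)
        level_labels[f.name] = labels

    if spec.missing_rate > 0:
        miss = {
            f.name: rng.random(n) < spec.missing_rate for f in spec.factor_set
        }
    else:
        miss = {f.name: np.zeros(n, dtype=bool) for f in spec.factor_set}

    records = []
    for i in range(n):
        sel: dict[str, str | None] = {}
        for f in spec.factor_set:
            if miss[f.name][i]:
                sel[f.name] = None
            else:
                sel[f.name] = level_labels[f.name][level_draws[f.name][i]]
        records.append(
            CaseControlRecord(
                is_case=bool(is_case[i]),
                age=int(ages[i]),
                sex=Sex(sexes[i]),
                race=spec.race,
                selections=sel,
            )
        )
    return records
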