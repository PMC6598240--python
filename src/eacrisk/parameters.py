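"""Input parameter tables for the risk calculator.

The calculator is driven entirely by small CSV parameter files: relative-risk
tables per risk factor (one file per Barrett's-esophagus stratum) and
age/sex/race-specific incidence and mortality rate tables.  This module
defines the validated in-memory representations and the loaders/writers.

CSV dialect: comma-separated, UTF-8, header row required, '.' decimal
separator.

Risk-factor files carry the columns
``factor, level, rr, ci_low, ci_high, prevalence, is_reference``;
rate files carry ``sex, race, age_lo, age_hi, rate`` (cause-specific
mortality files add a leading ``cause`` column).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "BEStratum",
    "Sex",
    "Race",
    "FactorLevel",
    "RiskFactor",
    "RiskFactorSet",
    "AgeGroupRate",
    "RateTable",
    "ParameterError",
    "ParseError",
    "ValidationError",
    "UnsupportedStratumError",
    "load_risk_factors",
    "save_risk_factors",
    "load_rate_table",
    "default_config_dir",
    "CONFIG_FILES",
]

_PREVALENCE_TOL = 1e-9

#: file names expected inside a calculator configuration directory
CONFIG_FILES = (
    "risk_factors_general.csv",
    "risk_factors_be.csv",
    "rates_incidence.csv",
    "rates_mortality_allcause.csv",
    "rates_mortality_causes.csv",
)


class ParameterError(Exception):
    """Base class for all parameter-table problems."""


class ParseError(ParameterError):
    """Raised when a parameter file cannot be parsed as the documented CSV dialect."""


class ValidationError(ParameterError):
    """Raised when a parsed table violates a model invariant."""


class UnsupportedStratumError(ParameterError):
    """Raised when a demographic stratum has no parameter data.

    Reliable inputs do not exist for every sex/race combination (black
    females in particular); such strata are represented by absent rows and
    must fail loudly rather than be extrapolated.
    """


class BEStratum(str, enum.Enum):
    """Diagnosed Barrett's-esophagus status, the calculator's top-level stratifier."""

    UNKNOWN_OR_NEGATIVE = "unknown_or_negative"
    POSITIVE = "positive"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Race(str, enum.Enum):
    WHITE = "white"
    BLACK = "black"


@dataclass(frozen=True)
class FactorLevel:
    """One exposure level of a risk factor.

    ``rr`` is the relative risk versus the factor's reference level, with a
    95% confidence interval ``(ci_low, ci_high)``; ``prevalence`` is the
    population proportion at this level.
    """

    label: str
    rr: float
    ci_low: float
    ci_high: float
    prevalence: float

    def __post_init__(self) -> None:
        if not (self.rr > 0):
            raise ValidationError(f"level {self.label!r}: rr must be > 0, got {self.rr}")
        if not (0 < self.ci_low <= self.rr <= self.ci_high):
            raise ValidationError(
                f"level {self.label!r}: require 0 < ci_low <= rr <= ci_high, "
                f"got ({self.ci_low}, {self.rr}, {self.ci_high})"
            )
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValidationError(
                f"level {self.label!r}: prevalence must be in [0, 1], got {self.prevalence}"
            )


@dataclass(frozen=True)
class RiskFactor:
    """A categorical risk factor with a designated reference level (rr = 1)."""

    name: str
    levels: tuple[FactorLevel, ...]
    reference_level: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 2:
            raise ValidationError(f"factor {self.name!r}: needs >= 2 levels")
        if not (0 <= self.reference_level < len(self.levels)):
            raise ValidationError(f"factor {self.name!r}: reference index out of range")
        ref = self.levels[self.reference_level]
        if not (ref.rr == 1.0 and ref.ci_low == 1.0 and ref.ci_high == 1.0):
            raise ValidationError(
                f"factor {self.name!r}: reference level {ref.label!r} must have "
                f"rr = ci_low = ci_high = 1"
            )
        total = sum(lv.prevalence for lv in self.levels)
        if abs(total - 1.0) > _PREVALENCE_TOL:
            raise ValidationError(
                f"factor {self.name!r}: level prevalences sum to {total!r}, expected 1"
            )
        labels = [lv.label for lv in self.levels]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"factor {self.name!r}: duplicate level labels")

    @property
    def reference(self) -> FactorLevel:
        return self.levels[self.reference_level]

    def level(self, label: str) -> FactorLevel:
        for lv in self.levels:
            if lv.label == label:
                return lv
        raise ValidationError(f"factor {self.name!r}: no level labelled {label!r}")


@dataclass(frozen=True)
class RiskFactorSet:
    """All risk factors active in one BE stratum.

    The two strata carry different factor sets: in diagnosed BE, segment
    length and dysplasia dominate, while family history and physical
    activity drop out for lack of progression data.
    """

    be_stratum: BEStratum
    factors: tuple[RiskFactor, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValidationError("factor names must be unique within a set")

    def __iter__(self):
        return iter(self.factors)

    def __len__(self) -> int:
        return len(self.factors)

    def factor(self, name: str) -> RiskFactor:
        for f in self.factors:
            if f.name == name:
                return f
        raise ValidationError(f"no factor named {name!r} in {self.be_stratum.value} set")

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)


@dataclass(frozen=True)
class AgeGroupRate:
    """Rate (events per person-year) in one closed 5-year age group."""

    age_lo: int
    age_hi: int
    rate: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.age_lo + self.age_hi)


@dataclass(frozen=True)
class RateTable:
    """Age-specific rates for one outcome in one (sex, race) stratum."""

    outcome: str
    sex: Sex
    race: Race
    rows: tuple[AgeGroupRate, ...]
    cause: str | None = None

    def __post_init__(self) -> None:
        rows = tuple(sorted(self.rows, key=lambda r: r.age_lo))
        object.__setattr__(self, "rows", rows)
        if not rows:
            raise ValidationError("rate table has no rows")
        for r in rows:
            if r.rate < 0:
                raise ValidationError(
                    f"negative rate {r.rate} in age group [{r.age_lo}, {r.age_hi}]"
                )
            if r.age_hi < r.age_lo:
                raise ValidationError(f"invalid age group [{r.age_lo}, {r.age_hi}]")
        for a, b in zip(rows, rows[1:]):
            if b.age_lo != a.age_hi + 1:
                kind = "overlap" if b.age_lo <= a.age_hi else "gap"
                raise ValidationError(
                    f"{kind} between age groups [{a.age_lo}, {a.age_hi}] and "
                    f"[{b.age_lo}, {b.age_hi}]"
                )
        if rows[0].age_lo > 40 or rows[-1].age_hi < 85:
            raise ValidationError(
                f"age groups cover [{rows[0].age_lo}, {rows[-1].age_hi}]; "
                f"must cover at least [40, 85+]"
            )

    @property
    def age_min(self) -> int:
        return self.rows[0].age_lo

    @property
    def age_max(self) -> int:
        return self.rows[-1].age_hi

    def midpoints(self) -> list[float]:
        return [r.midpoint for r in self.rows]

    def rates(self) -> list[float]:
        return [r.rate for r in self.rows]


# ---------------------------------------------------------------------------
# Loading / saving
# ---------------------------------------------------------------------------

_FACTOR_COLUMNS = ["factor", "level", "rr", "ci_low", "ci_high", "prevalence", "is_reference"]
_RATE_COLUMNS = ["sex", "race", "age_lo", "age_hi", "rate"]


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise ParseError(f"{path}: cannot parse as CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def load_risk_factors(path: str | Path, be_stratum: BEStratum | str) -> RiskFactorSet:
    """Load and validate a per-stratum risk-factor table.

    Raises :class:`ParseError` for malformed files and :class:`ValidationError`
    (naming the offending factor/level) when an invariant fails; a partially
    valid set is never returned.
    """
    be_stratum = BEStratum(be_stratum)
    df = _read_csv(path, _FACTOR_COLUMNS)
    factors: list[RiskFactor] = []
    for name, grp in df.groupby("factor", sort=False):
        levels = []
        ref_idx = None
        for i, (line_no, row) in enumerate(grp.iterrows()):
            try:
                lv = FactorLevel(
                    label=str(row["level"]),
                    rr=float(row["rr"]),
                    ci_low=float(row["ci_low"]),
                    ci_high=float(row["ci_high"]),
                    prevalence=float(row["prevalence"]),
                )
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: data row {line_no + 2}: non-numeric field: {exc}"
                ) from exc
            except ValidationError as exc:
                raise ValidationError(f"factor {name!r}: {exc}") from exc
            levels.append(lv)
            if _truthy(row["is_reference"]):
                if ref_idx is not None:
                    raise ValidationError(f"factor {name!r}: multiple reference levels")
                ref_idx = i
        if ref_idx is None:
            raise ValidationError(f"factor {name!r}: no reference level flagged")
        factors.append(RiskFactor(name=str(name), levels=tuple(levels), reference_level=ref_idx))
    return RiskFactorSet(be_stratum=be_stratum, factors=tuple(factors))


def _truthy(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes", "y"}
    return bool(value)


def save_risk_factors(factor_set: RiskFactorSet, path: str | Path) -> None:
    """Write a :class:`RiskFactorSet` in the documented CSV dialect (round-trips)."""
    rows = []
    for f in factor_set:
        for i, lv in enumerate(f.levels):
            rows.append(
                {
                    "factor": f.name,
                    "level": lv.label,
                    "rr": lv.rr,
                    "ci_low": lv.ci_low,
                    "ci_high": lv.ci_high,
                    "prevalence": lv.prevalence,
                    "is_reference": int(i == f.reference_level),
                }
            )
    pd.DataFrame(rows, columns=_FACTOR_COLUMNS).to_csv(path, index=False)


def load_rate_table(path: str | Path, outcome: str) -> list[RateTable]:
    """Load age-specific rate tables, one per (sex, race[, cause]) stratum present.

    Age groups within each stratum must be contiguous and non-overlapping and
    cover at least ages 40 through 85+.
    """
    df = _read_csv(path, _RATE_COLUMNS)
    has_cause = "cause" in df.columns
    keys = (["cause"] if has_cause else []) + ["sex", "race"]
    tables: list[RateTable] = []
    for key, grp in df.groupby(keys, sort=False):
        if has_cause:
            cause, sex, race = key
        else:
            cause = None
            sex, race = key
        rows = tuple(
            AgeGroupRate(int(r["age_lo"]), int(r["age_hi"]), float(r["rate"]))
            for _, r in grp.iterrows()
        )
        try:
            tables.append(
                RateTable(outcome=outcome, sex=Sex(sex), race=Race(race), rows=rows, cause=cause)
            )
        except ValidationError as exc:
            stratum = f"{sex}/{race}" + (f"/{cause}" if cause else "")
            raise ValidationError(f"{path}: stratum {stratum}: {exc}") from exc
    if not tables:
        raise ValidationError(f"{path}: no rate rows found")
    return tables


def default_config_dir() -> Path:
    """Directory holding the packaged default parameter files.

    The packaged tables are synthetic, literature-shaped placeholders so the
    calculator runs offline end to end; real SEER/NCHS rates and published
    relative-risk tables should replace them for substantive use.
    """
    return Path(resources.files("eacrisk").joinpath("data"))
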