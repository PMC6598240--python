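"""Case-control evaluation of the risk calculator's discrimination.

Pipeline mirrors how pooled case-control consortium data are prepared for a
risk-score evaluation:

- covariates absent from the source studies are randomly assigned: controls
  from published population prevalences, cases from the RR-tilted
  distribution so the implied odds ratios match the literature values;
- remaining missingness is filled by hot-deck multiple imputation within
  (case status, sex, 10-year age band) cells;
- controls are post-stratified to a reference (age-group, sex) population
  distribution, since study controls were frequency-matched to cases;
- every record is scored with the calculator and weighted threshold curves
  (sensitivity, specificity, ppv) plus the weighted AUC are computed.

ppv at a threshold is the weighted mean of the model-based 10-year risks of
the reweighted controls scoring at or above it — the expected fraction of
flagged population members who would develop the cancer — because
case-control data carry no population prevalence of their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import BEStratum, Race, RiskFactor, Sex, ValidationError
from .risk_engine import Calculator, IndividualProfile

__all__ = [
    "CaseControlRecord",
    "DiscriminationResult",
    "case_prevalence_from_or",
    "tilted_level_probs",
    "assign_unmeasured",
    "impute_missing",
    "reweight_controls",
    "score_records",
    "weighted_auc",
    "threshold_metrics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CaseControlRecord:
    """One study participant; ``selections`` values of ``None`` mean missing."""

    is_case: bool
    age: int
    sex: Sex
    race: Race
    selections: Mapping[str, str | None] = field(default_factory=dict)
    weight: float = 1.0
    risk_per_1000: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "race", Race(self.race))
        object.__setattr__(self, "selections", dict(self.selections))
        if self.weight < 0:
            raise ValidationError("record weight must be >= 0")
        if self.age < 40:
            raise ValidationError(f"record age must be >= 40, got {self.age}")


@dataclass(frozen=True)
class DiscriminationResult:
    """Threshold curves (per-1000 risk scale) and the weighted AUC with bootstrap CI."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    ppv: np.ndarray
    auc: float
    auc_ci: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_per_1000": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "ppv": self.ppv,
            }
        )


# ---------------------------------------------------------------------------
# Constrained assignment of unmeasured covariates
# ---------------------------------------------------------------------------

def case_prevalence_from_or(control_prev: float, odds_ratio: float) -> float:
    """Case prevalence implied by a control prevalence and a target odds ratio.

    ``p1 = OR*q / (1 + OR*q)`` with ``q`` the control odds; the case/control
    odds ratio of the result equals the input exactly.
    """
    if not 0.0 < control_prev < 1.0:
        raise ValidationError(f"control prevalence must be in (0, 1), got {control_prev}")
    if odds_ratio <= 0:
        raise ValidationError(f"odds ratio must be > 0, got {odds_ratio}")
    q = control_prev / (1.0 - control_prev)
    return odds_ratio * q / (1.0 + odds_ratio * q)


def tilted_level_probs(control_prevs: np.ndarray, rrs: np.ndarray) -> np.ndarray:
    """Multi-level generalization: case level probabilities ∝ control prevalence x RR."""
    control_prevs = np.asarray(control_prevs, dtype=float)
    rrs = np.asarray(rrs, dtype=float)
    w = control_prevs * rrs
    total = w.sum()
    if total <= 0:
        raise ValidationError("tilted distribution has zero mass")
    return w / total


def assign_unmeasured(
    records: Sequence[CaseControlRecord],
    factor: RiskFactor,
    control_prevalences: Mapping[str, float],
    seed: int,
) -> list[CaseControlRecord]:
    """Randomly assign a factor that the source studies did not measure.

    Controls draw levels from ``control_prevalences``; cases draw from the
    RR-tilted distribution, so empirical case/control odds ratios converge to
    the factor's RRs as n grows.  Deterministic given ``seed``.
    """
    for i, rec in enumerate(records):
        if rec.selections.get(factor.name) is not None:
            raise ValidationError(
                f"record {i}: factor {factor.name!r} already assigned; refusing to overwrite"
            )
    labels = [lv.label for lv in factor.levels]
    p_ctrl = np.array([control_prevalences[lab] for lab in labels], dtype=float)
    if abs(p_ctrl.sum() - 1.0) > 1e-9:
        raise ValidationError("control prevalences must sum to 1")
    rrs = np.array([lv.rr for lv in factor.levels], dtype=float)
    p_case = tilted_level_probs(p_ctrl, rrs)
    rng = np.random.default_rng(seed)
    is_case = np.array([r.is_case for r in records])
    draws = np.empty(len(records), dtype=int)
    u = rng.random(len(records))
    cum_ctrl = np.cumsum(p_ctrl)
    cum_case = np.cumsum(p_case)
    draws[~is_case] = np.searchsorted(cum_ctrl, u[~is_case], side="right")
    draws[is_case] = np.searchsorted(cum_case, u[is_case], side="right")
    draws = np.minimum(draws, len(labels) - 1)
    return [
        replace(rec, selections={**rec.selections, factor.name: labels[d]})
        for rec, d in zip(records, draws)
    ]


# ---------------------------------------------------------------------------
# Hot-deck multiple imputation
# ---------------------------------------------------------------------------

def _cell_key(rec: CaseControlRecord) -> tuple:
    return (rec.is_case, rec.sex, (rec.age // 10) * 10)


def impute_missing(
    records: Sequence[CaseControlRecord], seed: int, m: int = 10
) -> list[list[CaseControlRecord]]:
    """Hot-deck multiple imputation of missing factor selections.

    Each missing value is drawn from the observed level distribution among
    records matching on case status, sex and 10-year age band; cells with no
    donors fall back to the marginal observed distribution (logged).  Returns
    ``m`` independently completed copies of the record list.
    """
    factor_names = sorted({k for r in records for k in r.selections})
    donors: dict[str, dict[tuple, list[str]]] = {f: {} for f in factor_names}
    marginal: dict[str, list[str]] = {f: [] for f in factor_names}
    for rec in records:
        for f in factor_names:
            v = rec.selections.get(f)
            if v is not None:
                donors[f].setdefault(_cell_key(rec), []).append(v)
                marginal[f].append(v)
    rng = np.random.default_rng(seed)
    completions: list[list[CaseControlRecord]] = []
    for _ in range(m):
        completed = []
        for rec in records:
            missing = [f for f in factor_names if rec.selections.get(f) is None]
            if not missing:
                completed.append(rec)
                continue
            sel = dict(rec.selections)
            for f in missing:
                pool = donors[f].get(_cell_key(rec))
                if not pool:
                    pool = marginal[f]
                    logger.info(
                        "no donors for factor %r in cell %s; using marginal distribution",
                        f,
                        _cell_key(rec),
                    )
                if not pool:
                    raise ValidationError(f"factor {f!r}: no observed values to impute from")
                sel[f] = pool[rng.integers(len(pool))]
            completed.append(replace(rec, selections=sel))
        completions.append(completed)
    return completions


# ---------------------------------------------------------------------------
# Post-stratification of controls
# ---------------------------------------------------------------------------

def reweight_controls(
    records: Sequence[CaseControlRecord], reference: pd.DataFrame
) -> list[CaseControlRecord]:
    """Post-stratify control weights to a reference (age-group, sex) distribution.

    ``reference`` has columns ``age_lo, age_hi, sex, proportion``.  Control
    weights become reference proportion / sample proportion for the control's
    cell, renormalized to preserve the total control weight; case weights are
    untouched.  After reweighting the weighted control (age-group, sex)
    distribution equals the reference exactly.
    """
    ref = reference.reset_index(drop=True).copy()
    ref["sex"] = ref["sex"].map(Sex)
    props = ref["proportion"].to_numpy(dtype=float)
    props = props / props.sum()

    def cell_of(rec: CaseControlRecord) -> int:
        hits = ref.index[
            (ref["age_lo"] <= rec.age) & (rec.age <= ref["age_hi"]) & (ref["sex"] == rec.sex)
        ]
        if len(hits) == 0:
            raise ValidationError(
                f"control (age {rec.age}, {rec.sex.value}) matches no reference cell"
            )
        return int(hits[0])

    controls = [(i, rec) for i, rec in enumerate(records) if not rec.is_case]
    if not controls:
        return list(records)
    cells = np.array([cell_of(rec) for _, rec in controls])
    n_ctrl = len(controls)
    sample_counts = np.bincount(cells, minlength=len(ref))
    empty = [
        f"[{int(ref.age_lo[i])}, {int(ref.age_hi[i])}] {ref.sex[i].value}"
        for i in range(len(ref))
        if sample_counts[i] == 0 and props[i] > 0
    ]
    if empty:
        raise ValidationError(
            "reference cells with no sampled controls: " + "; ".join(empty)
        )
    raw = props[cells] / (sample_counts[cells] / n_ctrl)
    weights = raw * (n_ctrl / raw.sum())
    out = list(records)
    for (i, rec), w in zip(controls, weights):
        out[i] = replace(rec, weight=float(w))
    return out


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_records(
    records: Sequence[CaseControlRecord] | Sequence[Sequence[CaseControlRecord]],
    calculator: Calculator,
    be_stratum: BEStratum = BEStratum.UNKNOWN_OR_NEGATIVE,
) -> list[CaseControlRecord]:
    """Score records with the calculator; input may be one record list or ``m`` imputations.

    With multiple imputations the per-record risks are averaged across
    completions before thresholding.  Returns records with ``risk_per_1000``
    set; any engine failure is re-raised with the record index attached.
    """
    if records and isinstance(records[0], CaseControlRecord):
        imputations: list[Sequence[CaseControlRecord]] = [records]  # type: ignore[list-item]
    else:
        imputations = list(records)  # type: ignore[arg-type]
    n = len(imputations[0])
    risks = np.zeros(n)
    for completed in imputations:
        if len(completed) != n:
            raise ValidationError("imputed record sets differ in length")
        for i, rec in enumerate(completed):
            profile = IndividualProfile(
                age=min(int(rec.age), 89),
                sex=rec.sex,
                race=rec.race,
                be_stratum=be_stratum,
                selections={k: v for k, v in rec.selections.items()},
            )
            try:
                risks[i] += calculator.prob10(profile)
            except Exception as exc:
                raise type(exc)(f"record {i}: {exc}") from exc
    risks /= len(imputations)
    base = imputations[0]
    return [replace(rec, risk_per_1000=float(1000.0 * r)) for rec, r in zip(base, risks)]


# ---------------------------------------------------------------------------
# Weighted threshold metrics and AUC
# ---------------------------------------------------------------------------

def weighted_auc(
    case_scores: np.ndarray,
    case_weights: np.ndarray,
    ctrl_scores: np.ndarray,
    ctrl_weights: np.ndarray,
) -> float:
    """Weighted probability that a random case outscores a random control (ties count 1/2).

    Computed by sorting the control scores and accumulating weights, so it is
    O((n+m) log(n+m)) yet agrees with the exhaustive pairwise sum exactly.
    """
    order = np.argsort(ctrl_scores, kind="stable")
    s = ctrl_scores[order]
    w = ctrl_weights[order]
    cw = np.concatenate([[0.0], np.cumsum(w)])
    below = cw[np.searchsorted(s, case_scores, side="left")]
    upto = cw[np.searchsorted(s, case_scores, side="right")]
    ties = upto - below
    num = float(np.sum(case_weights * (below + 0.5 * ties)))
    den = float(case_weights.sum() * ctrl_weights.sum())
    if den == 0:
        raise ValidationError("zero total weight among cases or controls")
    return num / den


def threshold_metrics(
    records: Sequence[CaseControlRecord],
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> DiscriminationResult:
    """Weighted sensitivity/specificity/ppv curves over all observed risk thresholds, plus AUC.

    At threshold tau (per 1000): sensitivity is the weighted fraction of cases
    with risk >= tau, specificity the weighted fraction of controls with
    risk < tau, and ppv the weighted mean model-based risk of controls at or
    above tau (NaN where no control is flagged).  The AUC CI is a stratified
    percentile bootstrap (cases and controls resampled separately).
    """
    scored = [r for r in records if r.risk_per_1000 is not None]
    if len(scored) != len(records):
        raise ValidationError("all records must be scored before computing metrics")
    cases = [r for r in scored if r.is_case]
    ctrls = [r for r in scored if not r.is_case]
    if not cases or not ctrls:
        raise ValidationError("need at least one case and one control with positive weight")
    cs = np.array([r.risk_per_1000 for r in cases])
    cw = np.array([r.weight for r in cases])
    ks = np.array([r.risk_per_1000 for r in ctrls])
    kw = np.array([r.weight for r in ctrls])
    if cw.sum() <= 0 or kw.sum() <= 0:
        raise ValidationError("need positive total weight among cases and controls")

    thresholds = np.unique(np.concatenate([cs, ks]))
    # tail sums of weights for scores >= tau, via sorted cumulative weights
    def tail_weight(scores: np.ndarray, weights: np.ndarray) -> np.ndarray:
        order = np.argsort(scores, kind="stable")
        s, w = scores[order], weights[order]
        cum = np.concatenate([[0.0], np.cumsum(w)])
        idx = np.searchsorted(s, thresholds, side="left")
        return cum[-1] - cum[idx]

    sens = tail_weight(cs, cw) / cw.sum()
    spec = 1.0 - tail_weight(ks, kw) / kw.sum()
    flagged_w = tail_weight(ks, kw)
    flagged_risk = tail_weight(ks, kw * ks / 1000.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(flagged_w > 0, flagged_risk / np.where(flagged_w > 0, flagged_w, 1.0), np.nan)

    auc = weighted_auc(cs, cw, ks, kw)
    rng = np.random.default_rng(seed)
    boots = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        ci = rng.integers(len(cs), size=len(cs))
        ki = rng.integers(len(ks), size=len(ks))
        boots[b] = weighted_auc(cs[ci], cw[ci], ks[ki], kw[ki])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(lo, auc), max(hi, auc)
    return DiscriminationResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        auc=auc,
        auc_ci=(float(lo), float(hi)),
    )
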