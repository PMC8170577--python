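"""Risk models and the probability calculus that feeds the transition matrix.

External epidemiological risk equations (QDiabetes/Framingham-style for
incident T2D, QRISK/Framingham/UKPDS-style for first and recurrent
cardiovascular events) are represented as pluggable :class:`RiskModel`
objects mapping a risk-factor vector to a cumulative K-year risk.  The
engine annualises those risks geometrically and applies BMI-stratum
hazard ratios on the complementary-log scale so probabilities stay in
[0, 1].

Two model families are supported from coefficient files so published
coefficient sets can be dropped in:

* logistic: cumulative risk = expit(intercept + sum coef * transform(x));
* baseline-survival: risk = 1 - S0 ** exp(lp - lp_mean), the common
  Cox/Weibull risk-score form.

A documented toy logistic parameterisation ships for tests and examples
(see :func:`toy_registry`); it is monotone in BMI and in the glycemic
marker, which is all the validation workflow requires.

Prediabetes handling follows the model's stated assumptions: incident-T2D
equations are evaluated with the glycemic marker forced to 42 mmol/mol
(6.0%) for the prediabetes stratum; first CV events in prediabetes use
the normal-glucose-tolerance model, recurrent CV events use the T2D model.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .riskfactors import RiskFactorVector

logger = logging.getLogger(__name__)

__all__ = [
    "annual_probability",
    "compound_probability",
    "apply_hazard_ratio",
    "Population",
    "RiskModel",
    "LogisticRiskModel",
    "BaselineSurvivalRiskModel",
    "RiskModelRegistry",
    "HazardRatioTable",
    "t2d_incidence",
    "cv_event_probability",
    "complication_probability",
    "toy_registry",
    "PREDIABETES_HBA1C_PCT",
    "NGT_HBA1C_PCT",
    "DEFAULT_ACS_SHARE",
]

#: Glycemic marker forced when evaluating incident-T2D equations for the
#: prediabetes stratum: 42 mmol/mol, used as 6.0%.
PREDIABETES_HBA1C_PCT = 6.0
#: Mid-normal marker used for the normal-glucose-tolerance stratum (the
#: cohort HbA1c field describes the diabetic stratum, not NGT).
NGT_HBA1C_PCT = 5.4
#: Default share of composite CVD risk routed to ACS rather than stroke,
#: taken from the reference-group observed split (3.4 vs 4.4 per 1000 PY).
DEFAULT_ACS_SHARE = 3.4 / 7.8


# ---------------------------------------------------------------------------
# probability calculus


def annual_probability(cum_risk: float, horizon: int) -> float:
    """Convert a cumulative K-year risk to a constant per-cycle probability.

    Uses the geometric scheme p = 1 - (1 - R)^(1/K), whose K-cycle
    compounding round-trips to R.  A certain event stays certain.
    """
    if not 0.0 <= cum_risk <= 1.0:
        raise ValueError(f"cumulative risk {cum_risk} outside [0, 1]")
    if horizon < 1:
        raise ValueError("horizon must be >= 1 year")
    if cum_risk == 1.0:
        return 1.0
    return -math.expm1(math.log1p(-cum_risk) / horizon)


def compound_probability(p: float, years: int) -> float:
    """Inverse of :func:`annual_probability`: cumulative risk over ``years``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return -math.expm1(years * math.log1p(-p)) if p < 1.0 else 1.0


def apply_hazard_ratio(p: float, hr: float) -> float:
    """Apply a hazard/relative risk to a per-cycle probability.

    Rate-scale (complementary-log) application 1 - (1 - p)^hr, which is
    the identity at hr = 1 and keeps the result in [0, 1] for any hr > 0.
    For the small annual probabilities involved it agrees with naive
    multiplication to under 1e-4.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if p == 1.0:
        return 1.0
    return -math.expm1(hr * math.log1p(-p))


# ---------------------------------------------------------------------------
# risk models


class Population(enum.Enum):
    NGT = "NGT"
    PREDIABETES = "PREDIABETES"
    T2D = "T2D"
    ANY = "ANY"


_TRANSFORMS: dict[str, Callable[[float], float]] = {
    "identity": lambda x: x,
    "log": math.log,
    "square": lambda x: x * x,
}


@dataclass(frozen=True)
class Term:
    """One linear-predictor term: coefficient * transform(field - ref)."""

    field: str
    coefficient: float
    transform: str = "identity"
    ref: float = 0.0

    def value(self, rf: RiskFactorVector, overrides: Mapping[str, float]) -> float:
        x = overrides.get(self.field, getattr(rf, self.field))
        return self.coefficient * _TRANSFORMS[self.transform](x - self.ref)


@dataclass(frozen=True)
class RiskModel:
    """A risk equation slot: maps a risk-factor vector to cumulative risk."""

    name: str
    horizon_years: int
    population: Population
    evaluate_fn: Callable[[RiskFactorVector, Mapping[str, float]], float] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")

    def evaluate(self, rf: RiskFactorVector, **overrides: float) -> float:
        risk = float(self.evaluate_fn(rf, overrides))
        if not 0.0 <= risk <= 1.0:
            raise ValueError(f"model '{self.name}' returned risk {risk} outside [0, 1]")
        return risk

    def annual(self, rf: RiskFactorVector, **overrides: float) -> float:
        return annual_probability(self.evaluate(rf, **overrides), self.horizon_years)


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x)) if x > -700 else 0.0


@dataclass(frozen=True)
class LogisticRiskModel(RiskModel):
    """Cumulative K-year risk = expit(intercept + linear predictor)."""

    intercept: float = 0.0
    terms: tuple[Term, ...] = ()

    def __post_init__(self) -> None:
        super().__post_init__()
        object.__setattr__(self, "evaluate_fn", self._eval)

    def _eval(self, rf: RiskFactorVector, overrides: Mapping[str, float]) -> float:
        lp = self.intercept + sum(t.value(rf, overrides) for t in self.terms)
        return _expit(lp)


@dataclass(frozen=True)
class BaselineSurvivalRiskModel(RiskModel):
    """Cox-style score: risk = 1 - S0 ** exp(linear predictor)."""

    baseline_survival: float = 1.0
    terms: tuple[Term, ...] = ()

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0.0 < self.baseline_survival <= 1.0:
            raise ValueError("baseline survival must be in (0, 1]")
        object.__setattr__(self, "evaluate_fn", self._eval)

    def _eval(self, rf: RiskFactorVector, overrides: Mapping[str, float]) -> float:
        lp = sum(t.value(rf, overrides) for t in self.terms)
        return 1.0 - self.baseline_survival ** math.exp(lp)


def _terms_from_records(records: Sequence[Mapping]) -> tuple[Term, ...]:
    return tuple(
        Term(
            field=str(r["term"]),
            coefficient=float(r["coefficient"]),
            transform=str(r.get("transform", "identity") or "identity"),
            ref=float(r.get("ref", 0.0) or 0.0),
        )
        for r in records
        if str(r["term"]) not in ("intercept", "baseline_survival")
    )


def load_risk_model(path) -> RiskModel:
    """Load a risk model from a JSON or CSV coefficient file.

    JSON schema: ``{"name", "kind": "logistic"|"baseline_survival",
    "horizon_years", "population", "intercept"|"baseline_survival",
    "terms": [{"term", "coefficient", "transform", "ref"}, ...]}``.
    CSV files carry the term rows plus special rows ``intercept`` /
    ``baseline_survival`` and model metadata in ``# key: value`` header
    comments.
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            spec = json.load(fh)
        meta = spec
        records = spec.get("terms", [])
    else:
        meta = {}
        with open(path) as fh:
            header_lines = []
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
                else:
                    header_lines.append(line)
                    break
            header_lines += fh.readlines()
        from io import StringIO

        df = pd.read_csv(StringIO("".join(header_lines)))
        records = df.to_dict("records")
        for r in records:
            if str(r["term"]) == "intercept":
                meta["intercept"] = float(r["coefficient"])
            if str(r["term"]) == "baseline_survival":
                meta["baseline_survival"] = float(r["coefficient"])

    kind = str(meta.get("kind", "logistic"))
    common = dict(
        name=str(meta.get("name", path)),
        horizon_years=int(meta.get("horizon_years", 10)),
        population=Population(str(meta.get("population", "ANY"))),
        terms=_terms_from_records(records),
    )
    if kind == "logistic":
        return LogisticRiskModel(intercept=float(meta.get("intercept", 0.0)), **common)
    if kind == "baseline_survival":
        return BaselineSurvivalRiskModel(
            baseline_survival=float(meta.get("baseline_survival", 1.0)), **common
        )
    raise ValueError(f"unknown risk-model kind '{kind}'")


# ---------------------------------------------------------------------------
# registry


#: Slot names the cohort engine expects.
REGISTRY_SLOTS = (
    "t2d_incidence",
    "cv_first_ngt",
    "cv_first_t2d",
    "cv_recurrent_ngt",
    "cv_recurrent_t2d",
)


class RiskModelRegistry:
    """Named slots for the risk equations the engine consumes.

    Required slots: ``t2d_incidence`` (incident diabetes, evaluated per
    glycemic stratum), ``cv_first_ngt`` / ``cv_first_t2d`` (first CV
    event) and ``cv_recurrent_ngt`` / ``cv_recurrent_t2d`` (recurrent CV
    event).  Missing slots raise ``KeyError`` naming the slot.
    """

    def __init__(self, models: Mapping[str, RiskModel] | None = None) -> None:
        self._models: dict[str, RiskModel] = dict(models or {})

    def register(self, slot: str, model: RiskModel) -> None:
        self._models[slot] = model

    def __getitem__(self, slot: str) -> RiskModel:
        try:
            return self._models[slot]
        except KeyError:
            raise KeyError(
                f"risk-model registry has no model in slot '{slot}'"
            ) from None

    def __contains__(self, slot: str) -> bool:
        return slot in self._models


# ---------------------------------------------------------------------------
# hazard-ratio tables


@dataclass(frozen=True)
class HazardRatioStratum:
    bmi_low: float
    bmi_high: float
    hr: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError("hazard ratio must be positive")
        if self.bmi_high <= self.bmi_low:
            raise ValueError("empty BMI stratum")


@dataclass(frozen=True)
class HazardRatioTable:
    """BMI-stratified Cox hazard ratios for one outcome.

    Strata are half-open ``[low, high)`` and non-overlapping; exactly one
    stratum (the reference) has hr == 1.  BMI values outside all strata
    are clamped to the nearest stratum with a logged warning.
    """

    outcome: str
    strata: tuple[HazardRatioStratum, ...]

    def __post_init__(self) -> None:
        ordered = sorted(self.strata, key=lambda s: s.bmi_low)
        for a, b in zip(ordered, ordered[1:]):
            if b.bmi_low < a.bmi_high:
                raise ValueError(f"overlapping BMI strata in '{self.outcome}'")
        if sum(1 for s in self.strata if s.hr == 1.0) < 1:
            raise ValueError(f"no reference stratum (hr == 1) in '{self.outcome}'")
        object.__setattr__(self, "strata", tuple(ordered))

    def lookup(self, bmi: float) -> float:
        for s in self.strata:
            if s.bmi_low <= bmi < s.bmi_high:
                return s.hr
        # clamp to the nearest stratum
        if bmi < self.strata[0].bmi_low:
            nearest = self.strata[0]
        else:
            nearest = self.strata[-1]
        logger.warning(
            "BMI %.1f outside all '%s' HR strata; clamped to [%.1f, %.1f)",
            bmi,
            self.outcome,
            nearest.bmi_low,
            nearest.bmi_high,
        )
        return nearest.hr

    @property
    def reference(self) -> HazardRatioStratum:
        return next(s for s in self.strata if s.hr == 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (self.outcome, s.bmi_low, s.bmi_high, s.hr, s.ci_low, s.ci_high)
                for s in self.strata
            ],
            columns=["outcome", "bmi_low", "bmi_high", "hr", "ci_low", "ci_high"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, outcome: str) -> "HazardRatioTable":
        sub = df[df["outcome"] == outcome]
        if sub.empty:
            raise ValueError(f"no HR rows for outcome '{outcome}'")
        strata = tuple(
            HazardRatioStratum(
                float(r.bmi_low),
                float(r.bmi_high),
                float(r.hr),
                float(r.ci_low) if not pd.isna(r.ci_low) else None,
                float(r.ci_high) if not pd.isna(r.ci_high) else None,
            )
            for r in sub.itertuples(index=False)
        )
        return cls(outcome, strata)


# ---------------------------------------------------------------------------
# transition-probability operations


def t2d_incidence(
    rf: RiskFactorVector,
    stratum: str,
    model: RiskModel,
    ngt_hba1c_pct: float = NGT_HBA1C_PCT,
) -> float:
    """Annual probability of incident T2D for the NGT or prediabetes stratum.

    The prediabetes stratum is evaluated with the glycemic marker forced
    to 42 mmol/mol (6.0%); the NGT stratum with a mid-normal marker
    (default 5.4%), because the cohort HbA1c field describes the diabetic
    stratum.  The already-diabetic stratum is rejected.
    """
    stratum = str(stratum).upper()
    if stratum == "T2D":
        raise ValueError("T2D stratum is already diabetic; no incidence applies")
    if stratum not in ("NGT", "PREDIABETES"):
        raise ValueError(f"unknown glycemic stratum '{stratum}'")
    if model.population not in (Population.ANY, Population.NGT, Population.PREDIABETES):
        raise ValueError(
            f"model '{model.name}' targets population {model.population.value}"
        )
    marker = PREDIABETES_HBA1C_PCT if stratum == "PREDIABETES" else ngt_hba1c_pct
    return model.annual(rf, hba1c_pct=marker)


def cv_event_probability(
    rf: RiskFactorVector,
    stratum: str,
    history: str,
    registry: RiskModelRegistry,
    acs_share: float = DEFAULT_ACS_SHARE,
) -> tuple[float, float]:
    """Annual (ACS, stroke) event probabilities for one glycemic stratum.

    ``history`` is ``"first"`` or ``"recurrent"``.  Prediabetes maps to
    the NGT model for first events and to the T2D model for recurrent
    events.  The composite annual CVD probability is partitioned into ACS
    vs stroke by ``acs_share``.
    """
    stratum = str(stratum).upper()
    history = str(history).lower()
    if history not in ("first", "recurrent"):
        raise ValueError(f"history must be 'first' or 'recurrent', got '{history}'")
    if stratum not in ("NGT", "PREDIABETES", "T2D"):
        raise ValueError(f"unknown glycemic stratum '{stratum}'")
    if not 0.0 <= acs_share <= 1.0:
        raise ValueError("acs_share must be in [0, 1]")

    if history == "first":
        slot = "cv_first_t2d" if stratum == "T2D" else "cv_first_ngt"
    else:
        slot = "cv_recurrent_ngt" if stratum == "NGT" else "cv_recurrent_t2d"
    p = registry[slot].annual(rf)
    return p * acs_share, p * (1.0 - acs_share)


COMPLICATION_OUTCOMES = (
    "sleep_apnea",
    "knee_replacement",
    "colorectal",
    "endometrial_pm",
    "breast_pm",
)
_POSTMENOPAUSAL = ("endometrial_pm", "breast_pm")


def complication_probability(
    rf: RiskFactorVector,
    outcome: str,
    hr_table: HazardRatioTable,
    baseline_rate: float,
) -> float:
    """Annual probability of an overlay complication for the cohort.

    The reference-stratum baseline rate is scaled by the BMI-stratum HR
    on the complementary-log scale.  Postmenopausal cancers apply only to
    the female share of a cohort at or past menopause age: they return 0
    below menopause age and are weighted by the female share otherwise.
    """
    if outcome not in COMPLICATION_OUTCOMES:
        raise ValueError(f"unknown complication outcome '{outcome}'")
    if outcome in _POSTMENOPAUSAL:
        if rf.age < rf.menopause_age:
            return 0.0
        weight = rf.share_women
    else:
        weight = 1.0
    hr = hr_table.lookup(rf.bmi)
    return weight * apply_hazard_ratio(baseline_rate, hr)


# ---------------------------------------------------------------------------
# shipped toy parameterisation

# The toy coefficients below are not a published risk equation.  They are
# a documented, monotone stand-in chosen once to give realistic orders of
# magnitude for a middle-aged UK-style cohort (a few percent 10-year T2D
# risk at normal weight, rising steeply with BMI and with the glycemic
# marker; mid-single-digit 10-year CVD risk).  The validation workflow
# relies only on their monotonicity in BMI and glycemia.


def toy_t2d_model() -> LogisticRiskModel:
    """Toy logistic 10-year incident-T2D risk, monotone in BMI and HbA1c."""
    return LogisticRiskModel(
        name="toy-qd-logistic",
        horizon_years=10,
        population=Population.ANY,
        intercept=-5.0,
        terms=(
            Term("bmi", 0.16, ref=22.5),
            Term("hba1c_pct", 2.2, ref=5.4),
            Term("age", 0.015, ref=50.0),
        ),
    )


def _toy_cv_model(name: str, intercept: float) -> LogisticRiskModel:
    return LogisticRiskModel(
        name=name,
        horizon_years=10,
        population=Population.ANY,
        intercept=intercept,
        terms=(
            Term("age", 0.05, ref=50.0),
            Term("bmi", 0.03, ref=25.0),
            Term("sbp", 0.012, ref=130.0),
            Term("share_smokers", 0.6),
            Term("sex_share_women", -0.35),
        ),
    )


def toy_registry() -> RiskModelRegistry:
    """Registry of documented toy models filling every engine slot.

    Intercepts encode the usual risk ordering: diabetic > normoglycemic,
    recurrent > first event (roughly a doubling at each step).
    """
    return RiskModelRegistry(
        {
            "t2d_incidence": toy_t2d_model(),
            "cv_first_ngt": _toy_cv_model("toy-cv-first-ngt", -3.2),
            "cv_first_t2d": _toy_cv_model("toy-cv-first-t2d", -2.5),
            "cv_recurrent_ngt": _toy_cv_model("toy-cv-recurrent-ngt", -2.2),
            "cv_recurrent_t2d": _toy_cv_model("toy-cv-recurrent-t2d", -1.6),
        }
    )


def zero_registry() -> RiskModelRegistry:
    """Registry in which every event risk is exactly zero (for tests)."""

    def zero(name: str) -> RiskModel:
        return RiskModel(
            name=name,
            horizon_years=10,
            population=Population.ANY,
            evaluate_fn=lambda rf, ov: 0.0,
        )

    return RiskModelRegistry({slot: zero(slot) for slot in REGISTRY_SLOTS})
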