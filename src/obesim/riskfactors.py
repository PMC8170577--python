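"""Cohort risk-factor vector and its year-on-year dynamics.

The cohort is summarised by a single vector of cardio-metabolic risk
factors.  Each field is either *static* (fixed at baseline: height,
smoking share, triglycerides, female share, medication shares other than
antihypertensives, menopause age) or *dynamic* (age, BMI, SBP, lipids,
HbA1c in the diabetic stratum, diabetes duration).

Treatment effects are expressed as changes from baseline (BMI as a
percentage, SBP/lipids as absolute changes, HbA1c in percentage points).
When treatment stops, the induced deltas decay linearly back to zero over
a configurable catch-up period, after which natural drift (BMI increase
up to a stop age; HbA1c progression in the diabetic stratum) applies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

__all__ = [
    "RiskFactorVector",
    "TreatmentEffect",
    "TrajectoryPolicy",
    "STATIC_FIELDS",
    "advance_risk_factors",
    "freeze_bmi",
]


@dataclass(frozen=True)
class RiskFactorVector:
    """Baseline/current cardio-metabolic risk factors of the cohort.

    Units: age and durations in years, BMI in kg/m2, height in cm, SBP in
    mmHg, cholesterol and triglycerides in mg/dL, HbA1c in % (applies to
    the T2D stratum), shares as proportions in [0, 1].
    """

    age: float
    sex_share_women: float
    bmi: float
    height: float = 168.0
    sbp: float = 130.0
    total_chol: float = 200.0
    hdl_chol: float = 55.0
    hba1c_pct: float = 7.0
    t2d_duration: float = 0.0
    triglycerides: float = 130.0
    share_tg_ge_150: float = 0.3
    share_smokers: float = 0.4
    share_antihypertensive: float = 0.15
    share_lipid_lowering: float = 0.10
    menopause_age: float = 51.0

    def __post_init__(self) -> None:
        if self.bmi <= 0:
            raise ValueError("bmi must be positive")
        for f in (
            "sex_share_women",
            "share_tg_ge_150",
            "share_smokers",
            "share_antihypertensive",
            "share_lipid_lowering",
        ):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f}={v} outside [0, 1]")

    @property
    def share_women(self) -> float:
        return self.sex_share_women


# Fields that never change over the horizon (treatment or drift).
STATIC_FIELDS = (
    "sex_share_women",
    "height",
    "triglycerides",
    "share_tg_ge_150",
    "share_smokers",
    "share_lipid_lowering",
    "menopause_age",
)


@dataclass(frozen=True)
class TreatmentEffect:
    """Treatment-induced changes from baseline, active for ``duration`` years.

    ``bmi_pct_change`` is a percentage of baseline BMI (a -10 means a 10%
    reduction); the other deltas are absolute.  After treatment stops the
    deltas shrink linearly to zero over ``catchup_years``.
    """

    bmi_pct_change: float = 0.0
    sbp_abs_change: float = 0.0
    hdl_abs_change: float = 0.0
    tc_abs_change: float = 0.0
    hba1c_point_change: float = 0.0
    antihypertensive_share_change: float = 0.0
    duration: float = 0.0
    catchup_years: float = 0.0

    def __post_init__(self) -> None:
        if self.duration < 0 or self.catchup_years < 0:
            raise ValueError("duration and catchup_years must be >= 0")

    def scale_at(self, cycle: int) -> float:
        """Fraction of the full treatment delta active during ``cycle``.

        1.0 while on treatment (cycle <= duration), then a linear decay
        reaching 0 after ``catchup_years`` further years; with a zero
        catch-up the delta vanishes immediately at treatment stop.  With
        duration 3 and a 2-year catch-up a -3.0 delta is -3.0 at year 3,
        -1.5 at year 4 and 0 from year 5 on.
        """
        if cycle <= self.duration:
            return 1.0
        if self.catchup_years <= 0:
            return 0.0
        return max(0.0, 1.0 - (cycle - self.duration) / self.catchup_years)


@dataclass(frozen=True)
class TrajectoryPolicy:
    """Natural drift of the dynamic risk factors off treatment."""

    bmi_drift_per_year: float = 0.0
    bmi_drift_stop_age: float = 200.0
    hba1c_drift_per_year: float = 0.0

    @classmethod
    def frozen(cls) -> "TrajectoryPolicy":
        return cls(0.0, 0.0, 0.0)


def advance_risk_factors(
    rf: RiskFactorVector,
    cycle: int,
    effect: TreatmentEffect | None,
    policy: TrajectoryPolicy,
    baseline: RiskFactorVector | None = None,
) -> RiskFactorVector:
    """Return the risk-factor vector for the start of cycle ``cycle + 1``.

    ``baseline`` anchors treatment deltas and drift (defaults to ``rf``
    when the caller keeps no separate baseline); static fields are copied
    from it untouched.
    """
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    base = baseline if baseline is not None else rf

    next_cycle = cycle + 1
    scale = effect.scale_at(next_cycle) if effect is not None else 0.0
    off_treatment_years = 0.0
    if effect is None:
        start_drift = 0.0
    else:
        start_drift = effect.duration + effect.catchup_years
    if next_cycle > start_drift:
        off_treatment_years = next_cycle - start_drift

    # BMI: treated delta is a percentage of baseline; drift applies only
    # once treatment and catch-up are fully over, and stops at a preset age.
    bmi_delta = base.bmi * (effect.bmi_pct_change / 100.0) * scale if effect else 0.0
    drift_years = off_treatment_years
    if policy.bmi_drift_per_year and policy.bmi_drift_stop_age is not None:
        drift_years = min(
            drift_years, max(0.0, policy.bmi_drift_stop_age - base.age)
        )
    bmi = base.bmi + bmi_delta + policy.bmi_drift_per_year * drift_years

    sbp = base.sbp + (effect.sbp_abs_change * scale if effect else 0.0)
    hdl = base.hdl_chol + (effect.hdl_abs_change * scale if effect else 0.0)
    tc = base.total_chol + (effect.tc_abs_change * scale if effect else 0.0)
    hba1c = (
        base.hba1c_pct
        + (effect.hba1c_point_change * scale if effect else 0.0)
        + policy.hba1c_drift_per_year * off_treatment_years
    )
    antihyp = base.share_antihypertensive + (
        effect.antihypertensive_share_change * scale if effect else 0.0
    )

    return replace(
        base,
        age=rf.age + 1.0,
        t2d_duration=rf.t2d_duration + 1.0,
        bmi=max(bmi, 1e-6),
        sbp=sbp,
        hdl_chol=hdl,
        total_chol=tc,
        hba1c_pct=hba1c,
        share_antihypertensive=min(max(antihyp, 0.0), 1.0),
    )


def freeze_bmi(rf: RiskFactorVector, cycles: int) -> list[RiskFactorVector]:
    """Validation-mode trajectory: all dynamics off except age/duration.

    Returns the vectors at cycles 0..cycles inclusive.  Equivalent to
    :func:`advance_risk_factors` with no treatment effect and zero drift.
    """
    out = [rf]
    current = rf
    for c in range(cycles):
        current = advance_risk_factors(
            current, c, None, TrajectoryPolicy.frozen(), baseline=current
        )
        out.append(current)
    return out


def fields_equal_except(
    a: RiskFactorVector, b: RiskFactorVector, exempt: tuple[str, ...]
) -> bool:
    """Utility: all dataclass fields equal outside ``exempt``."""
    for f in dataclasses.fields(RiskFactorVector):
        if f.name in exempt:
            continue
        if getattr(a, f.name) != getattr(b, f.name):
            return False
    return True
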