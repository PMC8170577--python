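"""Background and event-adjusted mortality.

General-population mortality enters as an age/sex life table of annual
death probabilities (qx).  Event-year case fatalities and post-event
excess mortality are layered on top:

=====================  =======================  =========================
trigger                year of onset (F / M)    years post onset
=====================  =======================  =========================
myocardial infarction  30.00% / 32.00%          RR 1.30 on background qx
unstable angina        30.00% / 32.00%          RR 1.30 on background qx
stroke                 24.70% / 17.10%          RR 2.00 on background qx
knee replacement       0.30% (both sexes)       none
colorectal cancer      30.11%                   flat 4.31% annually
endometrial cancer     10.54%                   flat 4.31% annually
breast cancer          4.08%                    flat 4.31% annually
=====================  =======================  =========================

Relative risks apply to the age/sex-specific annual probability on the
complementary-log scale; adjusted mortality is never below background.
Sleep apnea carries no mortality effect.  When both a CV history and a
cancer adjustment apply, the maximum of the adjusted probabilities is
used by default ("max" stacking; "multiplicative" is available).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .risk import apply_hazard_ratio
from .states import Cancer, CVStatus, HealthState

logger = logging.getLogger(__name__)

__all__ = [
    "MortalityTable",
    "MortalityAdjustment",
    "default_adjustments",
    "base_mortality",
    "adjusted_mortality",
    "synthetic_life_table",
]


class MortalityTable:
    """Annual death probabilities qx by integer age and sex.

    Ages must be contiguous per sex; lookups above the oldest tabulated
    age carry the last value forward (with a warning), matching common
    life-table practice for open-ended terminal ages.
    """

    def __init__(self, rows: Mapping[tuple[int, str], float]) -> None:
        if not rows:
            raise ValueError("empty mortality table")
        self._rows: dict[tuple[int, str], float] = {}
        for (age, sex), q in rows.items():
            sex = str(sex).upper()
            if sex not in ("F", "M"):
                raise ValueError(f"sex must be F or M, got '{sex}'")
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"qx({age}, {sex}) = {q} outside [0, 1]")
            self._rows[(int(age), sex)] = float(q)
        self._max_age = {
            sex: max(a for (a, s) in self._rows if s == sex)
            for sex in {s for (_, s) in self._rows}
        }
        for sex, top in self._max_age.items():
            ages = sorted(a for (a, s) in self._rows if s == sex)
            if ages != list(range(ages[0], top + 1)):
                raise ValueError(f"ages for sex {sex} are not contiguous")

    def qx(self, age: float, sex: str) -> float:
        sex = str(sex).upper()
        if sex not in self._max_age:
            raise KeyError(f"no rows for sex '{sex}'")
        a = int(math.floor(age))
        top = self._max_age[sex]
        if a > top:
            logger.warning("age %s beyond table; carrying qx(%d, %s) forward", age, top, sex)
            a = top
        try:
            return self._rows[(a, sex)]
        except KeyError:
            raise KeyError(f"age {a} below tabulated range for sex '{sex}'") from None

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self._rows.items())
        return pd.DataFrame(
            [(a, s, q) for (a, s), q in rows], columns=["age", "sex", "qx"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MortalityTable":
        return cls({(int(r.age), str(r.sex)): float(r.qx) for r in df.itertuples(index=False)})

    @classmethod
    def from_csv(cls, path) -> "MortalityTable":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


@dataclass(frozen=True)
class MortalityAdjustment:
    """Mortality change triggered by an event or health state."""

    trigger: str
    onset_prob_f: float | None = None
    onset_prob_m: float | None = None
    post_rr: float | None = None
    post_flat_prob: float | None = None

    def __post_init__(self) -> None:
        for p in (self.onset_prob_f, self.onset_prob_m, self.post_flat_prob):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.post_rr is not None and self.post_rr <= 0:
            raise ValueError("relative risk must be positive")

    def onset_prob(self, female_share: float) -> float:
        if self.onset_prob_f is None or self.onset_prob_m is None:
            raise ValueError(f"trigger '{self.trigger}' has no onset probability")
        return female_share * self.onset_prob_f + (1 - female_share) * self.onset_prob_m


def default_adjustments() -> dict[str, MortalityAdjustment]:
    """The shipped event/state mortality adjustments (table above)."""
    return {
        "mi": MortalityAdjustment("mi", 0.30, 0.32, post_rr=1.30),
        "unstable_angina": MortalityAdjustment("unstable_angina", 0.30, 0.32, post_rr=1.30),
        "acs": MortalityAdjustment("acs", 0.30, 0.32, post_rr=1.30),
        "stroke": MortalityAdjustment("stroke", 0.247, 0.171, post_rr=2.00),
        "knee_replacement": MortalityAdjustment("knee_replacement", 0.003, 0.003),
        "colorectal": MortalityAdjustment(
            "colorectal", 0.3011, 0.3011, post_flat_prob=0.0431
        ),
        "endometrial_pm": MortalityAdjustment(
            "endometrial_pm", 0.1054, 0.1054, post_flat_prob=0.0431
        ),
        "breast_pm": MortalityAdjustment("breast_pm", 0.0408, 0.0408, post_flat_prob=0.0431),
    }


def base_mortality(age: float, sex: str | float, table: MortalityTable) -> float:
    """Background annual death probability.

    ``sex`` is ``"F"``/``"M"`` for a single-sex cohort, or the female
    share as a float in [0, 1] for a mixed cohort, in which case the two
    sex-specific probabilities are mixed linearly.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    if isinstance(sex, str):
        return table.qx(age, sex)
    share = float(sex)
    if not 0.0 <= share <= 1.0:
        raise ValueError("female share must be in [0, 1]")
    return share * table.qx(age, "F") + (1 - share) * table.qx(age, "M")


_CANCER_TRIGGER = {
    Cancer.COLORECTAL: "colorectal",
    Cancer.ENDOMETRIAL_PM: "endometrial_pm",
    Cancer.BREAST_PM: "breast_pm",
}


def adjusted_mortality(
    state: HealthState,
    onset_this_cycle: bool,
    age: float,
    sex: str | float,
    table: MortalityTable,
    adjustments: Mapping[str, MortalityAdjustment] | None = None,
    stacking: str = "max",
) -> float:
    """Annual death probability for a cohort fraction occupying ``state``.

    During the cycle an acute CV event or cancer has its onset, the
    event-year case fatality replaces background mortality (never going
    below it).  Post-onset years apply the trigger's relative risk to the
    background probability (CV) or a flat annual probability (cancer).
    ``stacking`` resolves states where several adjustments would apply:
    ``"max"`` (default) takes the largest adjusted probability,
    ``"multiplicative"`` compounds the relative risks.
    """
    if adjustments is None:
        adjustments = default_adjustments()
    if stacking not in ("max", "multiplicative"):
        raise ValueError("stacking must be 'max' or 'multiplicative'")
    if state.is_dead:
        return 1.0
    q_base = base_mortality(age, sex, table)
    female_share = (
        1.0 if sex == "F" else 0.0 if sex == "M" else float(sex)
    )

    def adj_for(trigger: str) -> MortalityAdjustment:
        try:
            return adjustments[trigger]
        except KeyError:
            raise KeyError(f"no mortality adjustment for trigger '{trigger}'") from None

    candidates: list[float] = []
    rrs: list[float] = []

    if state.cancer != Cancer.NONE:
        adj = adj_for(_CANCER_TRIGGER[state.cancer])
        if onset_this_cycle:
            candidates.append(adj.onset_prob(female_share))
        else:
            candidates.append(adj.post_flat_prob)
    elif state.cv == CVStatus.ACS_YEAR:
        candidates.append(adj_for("acs").onset_prob(female_share))
    elif state.cv == CVStatus.STROKE_YEAR:
        candidates.append(adj_for("stroke").onset_prob(female_share))
    elif state.cv == CVStatus.POST_ACS:
        rrs.append(adj_for("acs").post_rr)
    elif state.cv == CVStatus.POST_STROKE:
        rrs.append(adj_for("stroke").post_rr)

    if rrs:
        if stacking == "multiplicative":
            candidates.append(apply_hazard_ratio(q_base, math.prod(rrs)))
        else:
            candidates.extend(apply_hazard_ratio(q_base, rr) for rr in rrs)

    if not candidates:
        return q_base
    q = max(candidates) if stacking == "max" else max(candidates)
    return max(q, q_base)


def synthetic_life_table(
    a_f: float = 1.6e-5,
    b_f: float = 0.105,
    a_m: float = 2.6e-5,
    b_m: float = 0.100,
    age_min: int = 0,
    age_max: int = 105,
) -> MortalityTable:
    """Synthetic Gompertz life table, a stand-in for national life tables.

    The hazard is h(x) = a * exp(b * x) per sex, so the annual death
    probability is qx = 1 - exp(-a/b * (e^(b(x+1)) - e^(bx))).  Default
    shape/scale give life expectancies and adult qx magnitudes broadly
    typical of a contemporary high-income population (female mortality
    below male at all adult ages); qx is monotone non-decreasing in age.
    """
    for v in (a_f, b_f, a_m, b_m):
        if v <= 0:
            raise ValueError("Gompertz parameters must be positive")
    rows: dict[tuple[int, str], float] = {}
    ages = np.arange(age_min, age_max + 1)
    for sex, a, b in (("F", a_f, b_f), ("M", a_m, b_m)):
        cumhaz = a / b * (np.exp(b * (ages + 1)) - np.exp(b * ages))
        qx = 1.0 - np.exp(-cumhaz)
        for age, q in zip(ages, qx):
            rows[(int(age), sex)] = float(min(q, 1.0))
    return MortalityTable(rows)


def gompertz_survival(age0: float, years: float, a: float, b: float) -> float:
    """Closed-form Gompertz survivor function S(age0 -> age0 + years)."""
    return math.exp(-a / b * (math.exp(b * (age0 + years)) - math.exp(b * age0)))
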