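"""Cohort simulator: assembles per-cycle transition matrices and tallies events.

Each annual cycle the engine rebuilds the transition operator from the
current risk-factor vector:

1. a death probability per state (background, post-event relative risks,
   or acute-year case fatality for the tunnel states);
2. for survivors, independent attribute transitions — glycemic
   progression (incident T2D), CV events (first or recurrent, split into
   ACS vs stroke), and cancer onset (only from CV event-free states, and
   only on the no-CV-event branch) — combined multiplicatively so each
   row sums to exactly 1;
3. cancer onset-year case fatality is applied to the incident flux at
   entry (cancer states are not tunnels), whereas acute CV case fatality
   is faced while occupying the one-year tunnel state.

Event counts per cycle are the probability fluxes into the event states
scaled by the cohort size; person-years are the alive mass summed over
cycle ends (no half-cycle correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .mortality import (
    MortalityAdjustment,
    MortalityTable,
    adjusted_mortality,
    default_adjustments,
)
from .risk import (
    DEFAULT_ACS_SHARE,
    HazardRatioTable,
    RiskModelRegistry,
    complication_probability,
    cv_event_probability,
    t2d_incidence,
)
from .riskfactors import (
    RiskFactorVector,
    TrajectoryPolicy,
    TreatmentEffect,
    advance_risk_factors,
)
from .states import (
    DEAD,
    Cancer,
    CVStatus,
    Glycemic,
    HealthState,
    StateOccupancy,
    TransitionMatrix,
    enumerate_states,
)

__all__ = ["EventTally", "SimulationResult", "CohortSimulator", "build_transition_matrix"]

#: Outcomes tallied per cycle.
TALLY_OUTCOMES = (
    "t2d_onset",
    "acs",
    "stroke",
    "colorectal",
    "endometrial_pm",
    "breast_pm",
    "knee_replacement",
    "deaths",
)

#: Placeholder baseline annual rates for the overlay/cancer complications
#: in the reference BMI stratum.  The sources behind these outcomes are
#: cited, not tabulated, so these order-of-magnitude defaults are
#: explicitly user-configurable.
DEFAULT_BASELINE_COMPLICATION_RATES: dict[str, float] = {
    "colorectal": 5e-4,
    "endometrial_pm": 2e-4,
    "breast_pm": 1e-3,
    "knee_replacement": 1e-3,
    "sleep_apnea": 0.0,
}


@dataclass
class EventTally:
    """Per-cycle event counts for a cohort of ``n`` individuals."""

    n: float
    horizon: int
    per_cycle: pd.DataFrame  # one row per cycle, one column per outcome
    person_years: float
    sleep_apnea_person_years: float = 0.0

    def cumulative(self, outcome: str) -> float:
        return float(self.per_cycle[outcome].sum())

    def __post_init__(self) -> None:
        if (self.per_cycle.to_numpy() < -1e-12).any():
            raise ValueError("negative event counts")
        if self.person_years > self.n * self.horizon + 1e-9:
            raise ValueError("person-years exceed cohort size x horizon")


def event_rate(tally: EventTally, outcome: str) -> float:
    """Events per 1000 person-years over the simulated horizon."""
    if tally.person_years <= 0:
        raise ValueError("zero person-years")
    return tally.cumulative(outcome) / tally.person_years * 1000.0


@dataclass
class SimulationResult:
    occupancy: list[StateOccupancy]
    tally: EventTally
    risk_factors: list[RiskFactorVector]

    def occupancy_frame(self) -> pd.DataFrame:
        """One row per cycle, one column per state."""
        states = self.occupancy[0].states
        return pd.DataFrame(
            [occ.mass for occ in self.occupancy],
            columns=[s.name for s in states],
            index=pd.Index([occ.cycle_index for occ in self.occupancy], name="cycle"),
        )

    def rate(self, outcome: str) -> float:
        return event_rate(self.tally, outcome)


def build_transition_matrix(
    rf: RiskFactorVector,
    registry: RiskModelRegistry,
    life_table: MortalityTable,
    adjustments: Mapping[str, MortalityAdjustment] | None = None,
    hr_tables: Mapping[str, HazardRatioTable] | None = None,
    baseline_rates: Mapping[str, float] | None = None,
    acs_share: float = DEFAULT_ACS_SHARE,
    stacking: str = "max",
) -> TransitionMatrix:
    """Assemble the annual transition operator for the current cycle.

    ``hr_tables``/``baseline_rates`` configure the cancer overlays; if a
    cancer outcome has no HR table its incidence is zero.
    """
    adjustments = default_adjustments() if adjustments is None else adjustments
    hr_tables = hr_tables or {}
    baseline_rates = (
        DEFAULT_BASELINE_COMPLICATION_RATES if baseline_rates is None else baseline_rates
    )
    states = enumerate_states()
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    mat = np.zeros((n, n))
    female = rf.sex_share_women

    cancer_types = (Cancer.COLORECTAL, Cancer.ENDOMETRIAL_PM, Cancer.BREAST_PM)
    cancer_outcome = {
        Cancer.COLORECTAL: "colorectal",
        Cancer.ENDOMETRIAL_PM: "endometrial_pm",
        Cancer.BREAST_PM: "breast_pm",
    }
    # annual cancer incidence probabilities (shared across source states)
    p_cancer: dict[Cancer, float] = {}
    for ct in cancer_types:
        oc = cancer_outcome[ct]
        if oc in hr_tables:
            p_cancer[ct] = complication_probability(
                rf, oc, hr_tables[oc], baseline_rates.get(oc, 0.0)
            )
        else:
            p_cancer[ct] = 0.0
    cancer_onset_cf = {
        ct: adjustments[cancer_outcome[ct]].onset_prob(female) for ct in cancer_types
    }

    for s in states:
        i = index[s]
        if s.is_dead:
            mat[i, i] = 1.0
            continue
        if s.cancer != Cancer.NONE:
            q = adjusted_mortality(
                s, False, rf.age, female, life_table, adjustments, stacking
            )
            mat[i, index[DEAD]] = q
            mat[i, i] = 1.0 - q
            continue

        q = adjusted_mortality(
            s, s.cv in (CVStatus.ACS_YEAR, CVStatus.STROKE_YEAR),
            rf.age, female, life_table, adjustments, stacking,
        )
        surv = 1.0 - q
        mat[i, index[DEAD]] += q

        # glycemic branch
        if s.glycemic == Glycemic.T2D:
            g_dist = {Glycemic.T2D: 1.0}
        else:
            p_t2d = t2d_incidence(rf, s.glycemic.name, registry["t2d_incidence"])
            g_dist = {s.glycemic: 1.0 - p_t2d, Glycemic.T2D: p_t2d}

        # CV branch
        if s.cv == CVStatus.EVENT_FREE:
            p_acs, p_str = cv_event_probability(
                rf, s.glycemic.name, "first", registry, acs_share
            )
            total = p_acs + p_str
            if total > 1.0:  # competing-risk normalisation
                p_acs, p_str = p_acs / total, p_str / total
            cv_dist = {
                CVStatus.EVENT_FREE: 1.0 - p_acs - p_str,
                CVStatus.ACS_YEAR: p_acs,
                CVStatus.STROKE_YEAR: p_str,
            }
        elif s.cv == CVStatus.ACS_YEAR:
            cv_dist = {CVStatus.POST_ACS: 1.0}
        elif s.cv == CVStatus.STROKE_YEAR:
            cv_dist = {CVStatus.POST_STROKE: 1.0}
        elif s.cv == CVStatus.POST_ACS:
            p_acs, p_str = cv_event_probability(
                rf, s.glycemic.name, "recurrent", registry, acs_share
            )
            total = p_acs + p_str
            if total > 1.0:
                p_acs, p_str = p_acs / total, p_str / total
            cv_dist = {
                CVStatus.POST_ACS: 1.0 - p_acs - p_str,
                CVStatus.ACS_YEAR: p_acs,
                CVStatus.STROKE_YEAR: p_str,
            }
        else:  # POST_STROKE: recurrent events stay on the stroke branch
            p_acs, p_str = cv_event_probability(
                rf, s.glycemic.name, "recurrent", registry, acs_share
            )
            p_rec = min(p_acs + p_str, 1.0)
            cv_dist = {
                CVStatus.POST_STROKE: 1.0 - p_rec,
                CVStatus.STROKE_YEAR: p_rec,
            }

        for g, pg in g_dist.items():
            for cv, pcv in cv_dist.items():
                w = surv * pg * pcv
                if w == 0.0:
                    continue
                if s.cv == CVStatus.EVENT_FREE and cv == CVStatus.EVENT_FREE:
                    # cancer onset only on the no-CV-event branch
                    p_stay = 1.0 - sum(p_cancer.values())
                    mat[i, index[HealthState(g, cv)]] += w * p_stay
                    for ct in cancer_types:
                        if p_cancer[ct] == 0.0:
                            continue
                        cf = cancer_onset_cf[ct]
                        mat[i, index[HealthState(None, None, ct)]] += (
                            w * p_cancer[ct] * (1.0 - cf)
                        )
                        mat[i, index[DEAD]] += w * p_cancer[ct] * cf
                else:
                    mat[i, index[HealthState(g, cv)]] += w

    return TransitionMatrix(mat, states=states)


@dataclass
class CohortSimulator:
    """Advance a mixed-stratum closed cohort over an annual horizon.

    Parameters mirror the run configuration: the risk-model registry, a
    life table, optional treatment effect and trajectory policy, the
    cancer/overlay hazard-ratio tables with their reference baseline
    rates, the ACS share of composite CVD risk, and the prevalent
    sleep-apnea share (an attribute, not a state).
    """

    registry: RiskModelRegistry
    life_table: MortalityTable
    adjustments: Mapping[str, MortalityAdjustment] | None = None
    hr_tables: Mapping[str, HazardRatioTable] = field(default_factory=dict)
    baseline_rates: Mapping[str, float] | None = None
    treatment: TreatmentEffect | None = None
    trajectory: TrajectoryPolicy = field(default_factory=TrajectoryPolicy.frozen)
    acs_share: float = DEFAULT_ACS_SHARE
    sleep_apnea_share: float = 0.0
    stacking: str = "max"

    def initial_occupancy(
        self, glycemic_split: tuple[float, float, float]
    ) -> StateOccupancy:
        """Cohort entry: event-free, cancer-free, split across glycemic strata."""
        s_ngt, s_pre, s_t2d = glycemic_split
        if abs(s_ngt + s_pre + s_t2d - 1.0) > 1e-9:
            raise ValueError("glycemic shares must sum to 1")
        mass = {
            HealthState(Glycemic.NGT, CVStatus.EVENT_FREE): s_ngt,
            HealthState(Glycemic.PREDIABETES, CVStatus.EVENT_FREE): s_pre,
            HealthState(Glycemic.T2D, CVStatus.EVENT_FREE): s_t2d,
        }
        return StateOccupancy(mass)

    def run(
        self,
        rf: RiskFactorVector,
        glycemic_split: tuple[float, float, float],
        horizon: int,
        n: float = 100.0,
    ) -> SimulationResult:
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        occ = self.initial_occupancy(glycemic_split)
        states = occ.states
        index = {s: i for i, s in enumerate(states)}
        trace = [occ]
        rfs = [rf]
        rows = []
        person_years = 0.0

        current_rf = rf
        for cycle in range(horizon):
            m = build_transition_matrix(
                current_rf,
                self.registry,
                self.life_table,
                adjustments=self.adjustments,
                hr_tables=self.hr_tables,
                baseline_rates=self.baseline_rates,
                acs_share=self.acs_share,
                stacking=self.stacking,
            )
            flux = occ.mass[:, None] * m.matrix  # mass moving a -> b
            new = StateOccupancy(
                flux.sum(axis=0), cycle_index=occ.cycle_index + 1, states=states
            )

            counts = {oc: 0.0 for oc in TALLY_OUTCOMES}
            for a, ia in index.items():
                for b, ib in index.items():
                    f = flux[ia, ib]
                    if f == 0.0 or a is b:
                        continue
                    if b.is_dead and not a.is_dead:
                        counts["deaths"] += f
                    if not a.is_dead and not b.is_dead:
                        if (a.cancer == Cancer.NONE and b.cancer == Cancer.NONE
                                and a.glycemic != Glycemic.T2D and b.glycemic == Glycemic.T2D):
                            counts["t2d_onset"] += f
                        if b.cv == CVStatus.ACS_YEAR:
                            counts["acs"] += f
                        if b.cv == CVStatus.STROKE_YEAR:
                            counts["stroke"] += f
                        if a.cancer == Cancer.NONE and b.cancer != Cancer.NONE:
                            counts[
                                {
                                    Cancer.COLORECTAL: "colorectal",
                                    Cancer.ENDOMETRIAL_PM: "endometrial_pm",
                                    Cancer.BREAST_PM: "breast_pm",
                                }[b.cancer]
                            ] += f

            # cancer incidence flux that dies at entry still counts as incidence
            # (approximated by dividing the surviving flux by 1 - case fatality)
            for ct, oc in (
                (Cancer.COLORECTAL, "colorectal"),
                (Cancer.ENDOMETRIAL_PM, "endometrial_pm"),
                (Cancer.BREAST_PM, "breast_pm"),
            ):
                cf = (self.adjustments or default_adjustments())[oc].onset_prob(
                    current_rf.sex_share_women
                )
                if counts[oc] > 0 and cf < 1.0:
                    counts[oc] /= 1.0 - cf

            # knee replacement: overlay event on the alive cohort
            if "knee_replacement" in self.hr_tables:
                p_kr = complication_probability(
                    current_rf,
                    "knee_replacement",
                    self.hr_tables["knee_replacement"],
                    (self.baseline_rates or DEFAULT_BASELINE_COMPLICATION_RATES).get(
                        "knee_replacement", 0.0
                    ),
                )
                counts["knee_replacement"] = p_kr * occ.alive_mass

            rows.append({oc: counts[oc] * n for oc in TALLY_OUTCOMES})
            person_years += new.alive_mass * n
            occ = new
            trace.append(occ)
            current_rf = advance_risk_factors(
                current_rf, cycle, self.treatment, self.trajectory, baseline=rf
            )
            rfs.append(current_rf)

        per_cycle = pd.DataFrame(rows, index=pd.RangeIndex(1, horizon + 1, name="cycle"))
        tally = EventTally(
            n=n,
            horizon=horizon,
            per_cycle=per_cycle,
            person_years=person_years,
            sleep_apnea_person_years=self.sleep_apnea_share * person_years,
        )
        return SimulationResult(occupancy=trace, tally=tally, risk_factors=rfs)
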