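"""Health-state space and the annual-cycle Markov cohort engine.

The model tracks a closed cohort as probability mass spread over a finite
set of mutually exclusive health states.  States combine a glycemic stratum
(normal glucose tolerance, prediabetes, type 2 diabetes), a cardiovascular
history (event-free, acute ACS year, post-ACS, acute stroke year,
post-stroke), three obesity-related cancers, and an absorbing dead state.

The enumeration used here is:

* 15 cancer-free alive states: the full product of the 3 glycemic strata
  and the 5 CV statuses;
* 3 cancer states (colorectal, postmenopausal endometrial, postmenopausal
  breast).  Glycemic and CV detail is not tracked once cancer occurs:
  cancer carries a flat excess mortality and no further modelled
  transitions, so the extra detail would be inert;
* 1 absorbing dead state,

for 19 states in total.  Collapsing the acute/post distinction inside the
cancer branch, these aggregate to 18 obesity-related state families plus
death (see :func:`state_family`).

Transitions may never move against the severity partial order: glycemic
status is non-decreasing (NGT < prediabetes < T2D), CV history never
reverts to event-free, an acute year is a tunnel into its post-event
state, cancer type never changes once acquired, and death is absorbing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Glycemic",
    "CVStatus",
    "Cancer",
    "HealthState",
    "DEAD",
    "enumerate_states",
    "state_family",
    "is_allowed_transition",
    "glycemic_rank",
    "StateOccupancy",
    "TransitionMatrix",
    "MatrixDiagnostics",
    "validate_matrix",
    "step",
]

MASS_TOL = 1e-9


class Glycemic(enum.IntEnum):
    """Glycemic stratum, ordered by severity."""

    NGT = 0
    PREDIABETES = 1
    T2D = 2


class CVStatus(enum.IntEnum):
    """Cardiovascular history.

    The acute states (``ACS_YEAR``, ``STROKE_YEAR``) are one-cycle tunnel
    states: the cohort fraction that has an event spends the event year
    there (facing the event-year case fatality) and survivors move on to
    the corresponding post-event state.
    """

    EVENT_FREE = 0
    ACS_YEAR = 1
    POST_ACS = 2
    STROKE_YEAR = 3
    POST_STROKE = 4


class Cancer(enum.IntEnum):
    NONE = 0
    COLORECTAL = 1
    ENDOMETRIAL_PM = 2
    BREAST_PM = 3


_CV_SUCCESSORS: dict[CVStatus, frozenset[CVStatus]] = {
    CVStatus.EVENT_FREE: frozenset(
        {CVStatus.EVENT_FREE, CVStatus.ACS_YEAR, CVStatus.STROKE_YEAR}
    ),
    CVStatus.ACS_YEAR: frozenset({CVStatus.POST_ACS}),
    CVStatus.POST_ACS: frozenset(
        {CVStatus.POST_ACS, CVStatus.ACS_YEAR, CVStatus.STROKE_YEAR}
    ),
    CVStatus.STROKE_YEAR: frozenset({CVStatus.POST_STROKE}),
    # Recurrent events after a stroke stay on the stroke branch: routing a
    # post-stroke fraction through the ACS tunnel would erase its stroke
    # history, i.e. regress.
    CVStatus.POST_STROKE: frozenset({CVStatus.POST_STROKE, CVStatus.STROKE_YEAR}),
}


@dataclass(frozen=True)
class HealthState:
    """One mutually exclusive health state.

    The dead state and the cancer states carry no glycemic/CV attributes
    (``None``): dead because it is purely absorbing, cancer because no
    glycemic- or CV-dependent quantity is evaluated there.
    """

    glycemic: Glycemic | None
    cv: CVStatus | None
    cancer: Cancer = Cancer.NONE
    is_dead: bool = False

    def __post_init__(self) -> None:
        if self.is_dead:
            if self.glycemic is not None or self.cv is not None or self.cancer != Cancer.NONE:
                raise ValueError("dead state carries no other attributes")
        elif self.cancer != Cancer.NONE:
            if self.glycemic is not None or self.cv is not None:
                raise ValueError("cancer states do not track glycemic/CV detail")
        else:
            if self.glycemic is None or self.cv is None:
                raise ValueError("alive cancer-free states need glycemic and CV status")

    @property
    def name(self) -> str:
        if self.is_dead:
            return "dead"
        if self.cancer != Cancer.NONE:
            return self.cancer.name.lower()
        return f"{self.glycemic.name.lower()}/{self.cv.name.lower()}"

    def __repr__(self) -> str:  # keep traces readable
        return f"<{self.name}>"


DEAD = HealthState(None, None, Cancer.NONE, is_dead=True)


def enumerate_states() -> list[HealthState]:
    """Deterministic ordered enumeration of the 19 health states.

    Order: the 15 glycemic x CV products (glycemic outer, CV inner), the
    3 cancer states, then the single absorbing dead state last.
    """
    states = [
        HealthState(g, cv)
        for g in Glycemic
        for cv in CVStatus
    ]
    states += [
        HealthState(None, None, c)
        for c in (Cancer.COLORECTAL, Cancer.ENDOMETRIAL_PM, Cancer.BREAST_PM)
    ]
    states.append(DEAD)
    return states


def state_family(state: HealthState) -> str:
    """Map a state to its reporting family.

    The 19 internal states aggregate to 18 obesity-related families
    (15 glycemic x CV combinations + 3 cancers) plus ``dead``.
    """
    return state.name


def glycemic_rank(state: HealthState) -> int | None:
    """Severity rank of the glycemic stratum (NGT < prediabetes < T2D)."""
    return None if state.glycemic is None else int(state.glycemic)


def is_allowed_transition(a: HealthState, b: HealthState) -> bool:
    """True iff ``a -> b`` respects the severity partial order.

    Death is absorbing; glycemic status never decreases; CV history
    follows the tunnel/successor structure; cancer type is permanent and
    onset only occurs from CV event-free states.  Staying in place is
    always allowed (it is never a regression), even for the acute tunnel
    states, whose *engine-built* rows nonetheless always exit.
    """
    if a == b:
        return True
    if a.is_dead:
        return b.is_dead
    if b.is_dead:
        return True
    if a.cancer != Cancer.NONE:
        return b.cancer == a.cancer
    if b.cancer != Cancer.NONE:
        # onset of cancer, only modelled from CV event-free states
        return a.cv == CVStatus.EVENT_FREE
    if b.glycemic < a.glycemic:
        return False
    return b.cv in _CV_SUCCESSORS[a.cv]


class StateOccupancy:
    """Probability mass of the cohort over the enumerated states.

    Parameters
    ----------
    mass
        Mapping state -> probability, or an array aligned with
        ``enumerate_states()`` order.  Must be non-negative and sum to 1
        within 1e-9.
    cycle_index
        Years since cohort entry.
    """

    def __init__(
        self,
        mass: Mapping[HealthState, float] | np.ndarray | Iterable[float],
        cycle_index: int = 0,
        states: list[HealthState] | None = None,
    ) -> None:
        self.states = states if states is not None else enumerate_states()
        if isinstance(mass, Mapping):
            vec = np.zeros(len(self.states))
            index = {s: i for i, s in enumerate(self.states)}
            for s, p in mass.items():
                vec[index[s]] = p
        else:
            vec = np.asarray(list(mass), dtype=float)
            if vec.shape != (len(self.states),):
                raise ValueError(
                    f"mass vector length {vec.size} != {len(self.states)} states"
                )
        if (vec < -MASS_TOL).any():
            raise ValueError("negative occupancy mass")
        if abs(vec.sum() - 1.0) > 1e-6:
            raise ValueError(f"occupancy mass sums to {vec.sum():.12f}, not 1")
        self.mass = vec
        self.cycle_index = int(cycle_index)

    def __getitem__(self, state: HealthState) -> float:
        return float(self.mass[self.states.index(state)])

    @property
    def dead_mass(self) -> float:
        return self[DEAD]

    @property
    def alive_mass(self) -> float:
        return 1.0 - self.dead_mass

    def as_series(self) -> pd.Series:
        return pd.Series(self.mass, index=[s.name for s in self.states])


@dataclass
class MatrixDiagnostics:
    """Validation report for a transition matrix."""

    row_sum_errors: list[tuple[str, float]]
    negative_entries: list[tuple[str, str, float]]
    order_violations: list[tuple[str, str, float]]
    tol: float = MASS_TOL

    @property
    def ok(self) -> bool:
        return not (self.row_sum_errors or self.negative_entries or self.order_violations)

    def __str__(self) -> str:
        if self.ok:
            return "transition matrix OK"
        parts = []
        for name, s in self.row_sum_errors:
            parts.append(f"row '{name}' sums to {s:.9f}")
        for a, b, v in self.negative_entries:
            parts.append(f"negative entry {a} -> {b}: {v}")
        for a, b, v in self.order_violations:
            parts.append(f"severity-order violation {a} -> {b}: {v}")
        return "; ".join(parts)


class TransitionMatrix:
    """Row-stochastic annual transition operator over the health states."""

    def __init__(
        self,
        matrix: np.ndarray | Mapping[tuple[HealthState, HealthState], float],
        states: list[HealthState] | None = None,
    ) -> None:
        self.states = states if states is not None else enumerate_states()
        n = len(self.states)
        if isinstance(matrix, Mapping):
            arr = np.zeros((n, n))
            index = {s: i for i, s in enumerate(self.states)}
            for (a, b), p in matrix.items():
                try:
                    arr[index[a], index[b]] = p
                except KeyError as exc:  # malformed state reference
                    raise ValueError(f"unknown state in matrix: {exc}") from exc
        else:
            arr = np.asarray(matrix, dtype=float)
            if arr.shape != (n, n):
                raise ValueError(f"matrix shape {arr.shape} != ({n}, {n})")
        self.matrix = arr

    def __getitem__(self, key: tuple[HealthState, HealthState]) -> float:
        a, b = key
        return float(self.matrix[self.states.index(a), self.states.index(b)])

    def validate(self, tol: float = MASS_TOL) -> MatrixDiagnostics:
        return validate_matrix(self, tol=tol)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (from_state, to_state, probability) with zero rows omitted."""
        rows = []
        for i, a in enumerate(self.states):
            for j, b in enumerate(self.states):
                p = self.matrix[i, j]
                if p != 0.0:
                    rows.append((a.name, b.name, p))
        return pd.DataFrame(rows, columns=["from_state", "to_state", "probability"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, states: list[HealthState] | None = None) -> "TransitionMatrix":
        states = states if states is not None else enumerate_states()
        by_name = {s.name: s for s in states}
        entries: dict[tuple[HealthState, HealthState], float] = {}
        for row in df.itertuples(index=False):
            try:
                a, b = by_name[row.from_state], by_name[row.to_state]
            except KeyError as exc:
                raise ValueError(f"unknown state name in CSV: {exc}") from exc
            entries[(a, b)] = float(row.probability)
        return cls(entries, states=states)

    @classmethod
    def from_csv(cls, path, states: list[HealthState] | None = None) -> "TransitionMatrix":
        return cls.from_frame(
            pd.read_csv(path, float_precision="round_trip"), states=states
        )


def validate_matrix(m: TransitionMatrix, tol: float = MASS_TOL) -> MatrixDiagnostics:
    """Check row-stochasticity, non-negativity and the severity order.

    A severity-order violation is any strictly positive probability on a
    transition the partial order forbids (e.g. T2D back to prediabetes,
    or leaving the dead state).
    """
    row_sum_errors: list[tuple[str, float]] = []
    negative: list[tuple[str, str, float]] = []
    violations: list[tuple[str, str, float]] = []
    for i, a in enumerate(m.states):
        s = m.matrix[i].sum()
        if abs(s - 1.0) > tol:
            row_sum_errors.append((a.name, float(s)))
        for j, b in enumerate(m.states):
            p = m.matrix[i, j]
            if p < -tol:
                negative.append((a.name, b.name, float(p)))
            if p > tol and not is_allowed_transition(a, b):
                violations.append((a.name, b.name, float(p)))
    return MatrixDiagnostics(row_sum_errors, negative, violations, tol=tol)


def step(occ: StateOccupancy, m: TransitionMatrix, check: bool = True) -> StateOccupancy:
    """Advance the cohort occupancy one annual cycle.

    Raises ``ValueError`` (with the diagnostics message) if ``check`` is
    true and the matrix fails validation.
    """
    if occ.states != m.states:
        raise ValueError("occupancy and matrix use different state enumerations")
    if check:
        diag = validate_matrix(m)
        if not diag.ok:
            raise ValueError(f"invalid transition matrix: {diag}")
    new_mass = occ.mass @ m.matrix
    return StateOccupancy(new_mass, cycle_index=occ.cycle_index + 1, states=occ.states)
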