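"""Deterministic Markov cohort engine.

Builds the age-, sex- and cycle-specific 4×4 transition matrix from the
rate tables and propagates a cohort occupancy vector over the lifetime
horizon (100 one-year cycles by default, ages advancing one year per
cycle).

Conventions:

* state order is (NONADHERENT, ADHERENT, REMISSION, DEATH) = (A, B, C, D);
* an occupancy vector holds cohort fractions and always sums to 1;
* state membership during year ``t`` is the occupancy at the start of
  cycle ``t``; the transition applies at the end of the cycle (no
  half-cycle correction);
* DEATH is absorbing.

Adherence switching between A and B is not tabulated anywhere — it is the
intervention's lever — so the per-cycle A→B and B→A probabilities enter
through :class:`AdherenceDynamics`, resolved upstream by the scenario
layer from target adherent-share schedules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ParameterError, RateTables, Sex, lookup_rate

__all__ = [
    "A",
    "B",
    "C",
    "D",
    "AdherenceDynamics",
    "TransitionMatrix",
    "CohortTrajectory",
    "build_transition_matrix",
    "step",
    "run_cohort",
]

A, B, C, D = 0, 1, 2, 3

#: exit sums in (1, 1+_CLIP_TOL] are clipped silently-ish (warning); larger
#: sums up to _ERROR_TOL are proportionally renormalized; beyond that the
#: parameter set is considered implausible.
_CLIP_TOL = 1e-6
_ERROR_TOL = 0.5


@dataclass(frozen=True)
class AdherenceDynamics:
    """Per-cycle adherence switching probability schedules.

    ``prob_a_to_b[t]`` is the probability an untreated (A) person starts
    treatment during cycle ``t``; ``prob_b_to_a[t]`` the probability an
    adherent (B) person lapses.  Cycles past the end of a schedule hold
    its final value.
    """

    prob_a_to_b: np.ndarray
    prob_b_to_a: np.ndarray

    def __post_init__(self) -> None:
        for name in ("prob_a_to_b", "prob_b_to_a"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise ParameterError(f"{name} must be a nonempty 1-D schedule")
            if np.any((arr < 0) | (arr > 1)):
                raise ParameterError(f"{name} contains values outside [0, 1]")
            object.__setattr__(self, name, arr)

    @classmethod
    def constant(cls, prob_a_to_b: float, prob_b_to_a: float) -> "AdherenceDynamics":
        return cls(np.array([prob_a_to_b]), np.array([prob_b_to_a]))

    def a_to_b(self, cycle: int) -> float:
        return float(self.prob_a_to_b[min(cycle, self.prob_a_to_b.size - 1)])

    def b_to_a(self, cycle: int) -> float:
        return float(self.prob_b_to_a[min(cycle, self.prob_b_to_a.size - 1)])


@dataclass(frozen=True)
class TransitionMatrix:
    """A 4×4 row-stochastic matrix for one cycle of one demographic stratum."""

    matrix: np.ndarray
    age: int
    sex: Sex
    cycle_index: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ParameterError(f"transition matrix must be 4x4, got {m.shape}")
        object.__setattr__(self, "matrix", m)


def _resolve_row(exits: dict[int, float], diagonal: int, label: str) -> np.ndarray:
    """Assemble one matrix row from its exit probabilities.

    The diagonal is the complement of the exits.  Exit sums barely above 1
    (rounding noise) are clipped; clearly over-unit sums are proportionally
    renormalized with a warning; implausible sums raise.
    """
    row = np.zeros(4)
    s = sum(exits.values())
    if s > 1.0 + _ERROR_TOL:
        raise ParameterError(
            f"row {label}: exit probabilities sum to {s:.4f} > {1 + _ERROR_TOL}; "
            "parameter set implausible"
        )
    if s > 1.0:
        if s > 1.0 + 1e-12:  # pure float noise clips silently
            kind = "clipping" if s <= 1.0 + _CLIP_TOL else "renormalizing"
            warnings.warn(
                f"row {label}: exit probabilities sum to {s:.6g} > 1; {kind} to 1",
                RuntimeWarning,
                stacklevel=3,
            )
        exits = {k: v / s for k, v in exits.items()}
        s = 1.0
    for k, v in exits.items():
        row[k] = v
    row[diagonal] = 1.0 - s
    return row


def build_transition_matrix(
    tables: RateTables,
    dynamics: AdherenceDynamics,
    age: int,
    sex: Sex | str,
    cycle: int = 0,
) -> TransitionMatrix:
    """Transition matrix for one cycle at the given age and sex.

    Exits: A→{B (switching), C (remission), D (epilepsy mortality,
    nonadherent)}; B→{A (lapse), C (remission, same rate as from A),
    D (epilepsy mortality, adherent)}; C→{A, B (relapse, split by
    ``relapse_split_to_adherent``), D (background mortality)}; D absorbs.
    Diagonals are complements so each row sums to exactly 1.
    """
    if age < 0:
        raise ParameterError(f"negative age {age}")
    sex = Sex.coerce(sex)
    rem = lookup_rate(tables, "remission", age, sex)
    mort_non = lookup_rate(tables, "mortality_nonadherent", age)
    mort_adh = lookup_rate(tables, "mortality_adherent", age)
    relapse = lookup_rate(tables, "relapse", age)
    bg = lookup_rate(tables, "background_mortality", age, sex)
    split = tables.relapse_split_to_adherent
    p_ab = dynamics.a_to_b(cycle)
    p_ba = dynamics.b_to_a(cycle)

    m = np.empty((4, 4))
    m[A] = _resolve_row({B: p_ab, C: rem, D: mort_non}, A, "NONADHERENT")
    m[B] = _resolve_row({A: p_ba, C: rem, D: mort_adh}, B, "ADHERENT")
    m[C] = _resolve_row(
        {A: relapse * (1.0 - split), B: relapse * split, D: bg}, C, "REMISSION"
    )
    m[D] = np.array([0.0, 0.0, 0.0, 1.0])
    return TransitionMatrix(matrix=m, age=age, sex=sex, cycle_index=cycle)


def step(occupancy: np.ndarray, matrix: TransitionMatrix | np.ndarray) -> np.ndarray:
    """One cohort propagation step: ``occupancy · M``."""
    occ = np.asarray(occupancy, dtype=float)
    m = matrix.matrix if isinstance(matrix, TransitionMatrix) else np.asarray(matrix)
    if occ.shape != (4,) or m.shape != (4, 4):
        raise ParameterError(
            f"dimension mismatch: occupancy {occ.shape}, matrix {m.shape}"
        )
    return occ @ m


@dataclass(frozen=True)
class CohortTrajectory:
    """Cohort occupancy over time: ``occupancy[t]`` at the start of cycle ``t``.

    Shape ``(horizon + 1, 4)``; the final row is the occupancy after the
    last cycle.
    """

    occupancy: np.ndarray
    entry_age: int
    sex: Sex
    horizon: int

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.shape != (self.horizon + 1, 4):
            raise ParameterError(
                f"trajectory shape {occ.shape} != ({self.horizon + 1}, 4)"
            )
        object.__setattr__(self, "occupancy", occ)

    def living(self) -> np.ndarray:
        """Fraction alive (A+B+C) at the start of each cycle."""
        return 1.0 - self.occupancy[:, D]

    def adherent_share(self) -> np.ndarray:
        """B / (A + B) per cycle (NaN where no one has epilepsy)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            ab = self.occupancy[:, A] + self.occupancy[:, B]
            return np.where(ab > 0, self.occupancy[:, B] / ab, np.nan)

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: cycle, age and the four occupancy columns."""
        cycles = np.arange(self.horizon + 1)
        return pd.DataFrame(
            {
                "cycle": cycles,
                "age": self.entry_age + cycles,
                "nonadherent": self.occupancy[:, A],
                "adherent": self.occupancy[:, B],
                "remission": self.occupancy[:, C],
                "death": self.occupancy[:, D],
            }
        )


def run_cohort(
    tables: RateTables,
    dynamics: AdherenceDynamics,
    entry_age: int,
    sex: Sex | str,
    initial_occupancy: np.ndarray,
    horizon: int = 100,
) -> CohortTrajectory:
    """Propagate a cohort for *horizon* one-year cycles.

    The cohort enters with epilepsy (all mass in A and B: remission and
    death start empty) and ages one year per cycle; matrices are rebuilt
    each cycle at the current age.
    """
    if horizon < 0:
        raise ParameterError(f"horizon must be >= 0, got {horizon}")
    sex = Sex.coerce(sex)
    init = np.asarray(initial_occupancy, dtype=float)
    if init.shape != (4,):
        raise ParameterError(f"initial occupancy must have 4 entries, got {init.shape}")
    if np.any(init < 0) or abs(init.sum() - 1.0) > 1e-9:
        raise ParameterError("initial occupancy must be nonnegative and sum to 1")
    if init[C] != 0 or init[D] != 0:
        raise ParameterError(
            "cohort must enter in the epilepsy states (REMISSION and DEATH start at 0)"
        )

    occ = np.empty((horizon + 1, 4))
    occ[0] = init
    for t in range(horizon):
        tm = build_transition_matrix(tables, dynamics, entry_age + t, sex, t)
        occ[t + 1] = occ[t] @ tm.matrix
    return CohortTrajectory(occupancy=occ, entry_age=entry_age, sex=sex, horizon=horizon)
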