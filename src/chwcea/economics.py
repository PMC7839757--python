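"""QALY and cost accrual, ICER computation and threshold classification.

Rewards follow the cohort engine's convention: the occupancy at the start
of cycle ``t`` earns that year's utility and cost.  Accrual is undiscounted
by default; a discount rate is exposed for extension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .engine import CohortTrajectory
from .params import (
    CostModel,
    ParameterError,
    Thresholds,
    UtilitySet,
    convert_currency,
)

__all__ = [
    "COST_RULES",
    "CostBreakdown",
    "ArmOutcome",
    "CEAResult",
    "accrue_qalys",
    "accrue_costs",
    "evaluate_arm",
    "compute_icer",
    "classify_threshold",
]

#: How the per-person program cost accrues over the horizon:
#: ``all-cycles`` charges every cycle regardless of survival,
#: ``alive-cycles`` weights by the living fraction, ``none`` charges nothing
#: (the comparator arm).
COST_RULES = ("all-cycles", "alive-cycles", "none")


def _discount_weights(horizon: int, rate: float) -> np.ndarray:
    if rate < 0:
        raise ParameterError(f"discount rate must be >= 0, got {rate}")
    return 1.0 / (1.0 + rate) ** np.arange(horizon)


def accrue_qalys(
    trajectory: CohortTrajectory,
    utilities: UtilitySet,
    discount_rate: float = 0.0,
) -> float:
    """Lifetime QALYs per cohort member: Σ_t occupancy(t) · utility."""
    w = _discount_weights(trajectory.horizon, discount_rate)
    per_cycle = trajectory.occupancy[:-1] @ utilities.as_vector()
    return float(np.sum(w * per_cycle))


@dataclass(frozen=True)
class CostBreakdown:
    """Cost component of an arm: per-state accrual plus the program budget."""

    state_cost_zar: float
    program_cost_zar: float
    per_cycle_state_cost: np.ndarray
    cost_rule: str
    cost_level: str

    @property
    def total_zar(self) -> float:
        return self.state_cost_zar + self.program_cost_zar


def accrue_costs(
    trajectory: CohortTrajectory,
    cost: CostModel,
    intervention_cost_per_person_year: float = 0.0,
    intervention_cost_rule: str = "none",
    cost_level: str = "central",
    discount_rate: float = 0.0,
) -> CostBreakdown:
    """Lifetime costs per cohort member in ZAR.

    State costs accrue on the start-of-cycle occupancy at the chosen
    ``cost_level`` (central / low / high, the ±15% bounds in the shipped
    fixture).  The program component follows ``intervention_cost_rule``.
    """
    if intervention_cost_rule not in COST_RULES:
        raise ParameterError(
            f"unknown intervention cost rule {intervention_cost_rule!r}; "
            f"expected one of {COST_RULES}"
        )
    if intervention_cost_per_person_year < 0:
        raise ParameterError("intervention cost per person-year must be >= 0")
    w = _discount_weights(trajectory.horizon, discount_rate)
    per_cycle = trajectory.occupancy[:-1] @ cost.state_cost_vector(cost_level)
    state_cost = float(np.sum(w * per_cycle))

    if intervention_cost_rule == "none":
        program = 0.0
    elif intervention_cost_rule == "all-cycles":
        program = intervention_cost_per_person_year * float(np.sum(w))
    else:  # alive-cycles
        living = trajectory.living()[:-1]
        program = intervention_cost_per_person_year * float(np.sum(w * living))
    return CostBreakdown(
        state_cost_zar=state_cost,
        program_cost_zar=program,
        per_cycle_state_cost=w * per_cycle,
        cost_rule=intervention_cost_rule,
        cost_level=cost_level,
    )


@dataclass(frozen=True)
class ArmOutcome:
    """Lifetime QALYs and costs per cohort member for one strategy arm."""

    name: str
    lifetime_qalys: float
    lifetime_cost_zar: float
    costs: CostBreakdown

    def to_dict(self) -> dict:
        return {
            "arm": self.name,
            "lifetime_qalys": self.lifetime_qalys,
            "lifetime_cost_zar": self.lifetime_cost_zar,
            "state_cost_zar": self.costs.state_cost_zar,
            "program_cost_zar": self.costs.program_cost_zar,
        }


def evaluate_arm(
    name: str,
    trajectory: CohortTrajectory,
    utilities: UtilitySet,
    cost: CostModel,
    intervention_cost_per_person_year: float = 0.0,
    intervention_cost_rule: str = "none",
    cost_level: str = "central",
    discount_rate: float = 0.0,
) -> ArmOutcome:
    """Accrue both QALYs and costs for one arm of the comparison."""
    qalys = accrue_qalys(trajectory, utilities, discount_rate)
    costs = accrue_costs(
        trajectory,
        cost,
        intervention_cost_per_person_year,
        intervention_cost_rule,
        cost_level,
        discount_rate,
    )
    return ArmOutcome(
        name=name,
        lifetime_qalys=qalys,
        lifetime_cost_zar=costs.total_zar,
        costs=costs,
    )


def classify_threshold(icer_intl_dollar: float, thresholds: Thresholds) -> dict[str, bool]:
    """Compare an I$/QALY ratio against the WTP and 1×GDP thresholds (inclusive)."""
    return {
        "below_wtp": icer_intl_dollar <= thresholds.wtp_intl_dollar,
        "below_gdp": icer_intl_dollar <= thresholds.gdp_threshold_intl_dollar,
    }


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of an intervention arm against a comparator."""

    comparator: ArmOutcome
    intervention: ArmOutcome
    delta_cost_zar: float
    delta_qalys: float
    icer_zar_per_qaly: float | None
    icer_intl_dollar_per_qaly: float | None
    dominance_flag: str
    threshold_verdicts: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "comparator": self.comparator.to_dict(),
            "intervention": self.intervention.to_dict(),
            "delta_cost_zar": self.delta_cost_zar,
            "delta_qalys": self.delta_qalys,
            "icer_zar_per_qaly": self.icer_zar_per_qaly,
            "icer_intl_dollar_per_qaly": self.icer_intl_dollar_per_qaly,
            "dominance_flag": self.dominance_flag,
            "threshold_verdicts": dict(self.threshold_verdicts),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def table_row(self) -> dict:
        """Presentation row: currency to whole units, QALYs to 2 decimals."""
        return {
            "delta_qalys": round(self.delta_qalys, 2),
            "delta_cost_zar": round(self.delta_cost_zar),
            "icer_zar_per_qaly": None
            if self.icer_zar_per_qaly is None
            else round(self.icer_zar_per_qaly),
            "icer_intl_dollar_per_qaly": None
            if self.icer_intl_dollar_per_qaly is None
            else round(self.icer_intl_dollar_per_qaly),
            "dominance": self.dominance_flag,
            **{k: v for k, v in self.threshold_verdicts.items()},
        }


def compute_icer(
    comparator: ArmOutcome,
    intervention: ArmOutcome,
    cost: CostModel,
    thresholds: Thresholds,
    zero_effect_tol: float = 1e-12,
) -> CEAResult:
    """Incremental cost-effectiveness of *intervention* vs *comparator*.

    The ICER is Δcost/ΔQALY, reported in ZAR and international dollars per
    QALY.  A zero QALY difference is flagged rather than raised; dominance
    (cheaper *and* more effective) and dominated cases are labeled.
    """
    delta_cost = intervention.lifetime_cost_zar - comparator.lifetime_cost_zar
    delta_q = intervention.lifetime_qalys - comparator.lifetime_qalys

    if abs(delta_q) <= zero_effect_tol:
        flag = "zero-effect"
        icer_zar = icer_intl = None
        verdicts: dict[str, bool] = {}
    else:
        if delta_q > 0 and delta_cost < 0:
            flag = "dominant"
        elif delta_q < 0 and delta_cost > 0:
            flag = "dominated"
        else:
            flag = "tradeoff"
        icer_zar = delta_cost / delta_q
        icer_intl = convert_currency(delta_cost, cost) / delta_q
        verdicts = classify_threshold(icer_intl, thresholds)

    return CEAResult(
        comparator=comparator,
        intervention=intervention,
        delta_cost_zar=delta_cost,
        delta_qalys=delta_q,
        icer_zar_per_qaly=icer_zar,
        icer_intl_dollar_per_qaly=icer_intl,
        dominance_flag=flag,
        threshold_verdicts=verdicts,
    )
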