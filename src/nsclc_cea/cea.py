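"""Discounted accumulation and the incremental comparison.

Life-years, QALYs and costs are all discounted with the same annual rate
(converted to the cycle grid by compounding on fractional years).  QALYs
weight PFS occupancy by the arm-specific PFS utility and PD occupancy by
the shared post-progression utility.  The incremental cost-effectiveness
ratio (ICER) is ΔC/ΔE; sign patterns where a ratio is meaningless are
reported as dominance labels, never as signed infinities.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple

import numpy as np

from .economics import CostBreakdown, cycle_costs
from .markov import CohortTrace, discount_factor, run_cohort
from .parameters import ModelSettings, Scenario, UtilityInputs

__all__ = [
    "ArmResult",
    "CEAResult",
    "Dominance",
    "ScenarioResult",
    "accumulate",
    "compare",
    "nmb",
    "evaluate",
]


class Dominance(str, Enum):
    NONE = "none"
    INTERVENTION_DOMINANT = "intervention_dominant"
    INTERVENTION_DOMINATED = "intervention_dominated"


@dataclass(frozen=True)
class ArmResult:
    """Totals for one arm; ``*_undiscounted`` twins carry no time preference."""

    total_cost: float
    ly: float
    qaly: float
    total_cost_undiscounted: float
    ly_undiscounted: float
    qaly_undiscounted: float

    def __post_init__(self):
        if self.qaly > self.ly + 1e-9:
            raise ValueError("QALYs cannot exceed life-years")


@dataclass(frozen=True)
class CEAResult:
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_per_qaly: Optional[float]
    icer_per_ly: Optional[float]
    dominance: Dominance = Dominance.NONE


def _half_cycle(occ: np.ndarray) -> np.ndarray:
    """Trapezoid occupancy: average of cycle-start and next-cycle-start."""
    nxt = np.concatenate([occ[1:], [occ[-1]]])
    return 0.5 * (occ + nxt)


def accumulate(trace: CohortTrace, costs: CostBreakdown,
               utilities: UtilityInputs, arm_role: str,
               settings: ModelSettings) -> ArmResult:
    """Accumulate (discounted and undiscounted) cost, LY and QALY totals."""
    n = trace.n_cycles
    if costs.drug.size != n:
        raise ValueError("cost breakdown length does not match trace")
    t = np.arange(n)
    d = discount_factor(settings.annual_discount_rate, t,
                        settings.cycle_length_days)
    cyc_years = settings.cycle_length_years
    u_pfs = (utilities.u_pfs_intervention if arm_role == "intervention"
             else utilities.u_pfs_comparator)

    pfs, pd_state = trace.pfs, trace.pd
    flow = costs.per_cycle_total
    if settings.half_cycle_correction:
        pfs, pd_state = _half_cycle(pfs), _half_cycle(pd_state)
        flow = _half_cycle(flow)

    ly_flow = (pfs + pd_state) * cyc_years
    q_flow = (u_pfs * pfs + utilities.u_pd * pd_state) * cyc_years
    one_time = float(sum(costs.one_time.values()))  # charged at cycle 0

    return ArmResult(
        total_cost=float(np.sum(flow * d) + one_time),
        ly=float(np.sum(ly_flow * d)),
        qaly=float(np.sum(q_flow * d)),
        total_cost_undiscounted=float(np.sum(flow) + one_time),
        ly_undiscounted=float(np.sum(ly_flow)),
        qaly_undiscounted=float(np.sum(q_flow)),
    )


def compare(intervention: ArmResult, comparator: ArmResult) -> CEAResult:
    """Incremental comparison (intervention minus comparator)."""
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.qaly - comparator.qaly
    d_ly = intervention.ly - comparator.ly

    dominance = Dominance.NONE
    if d_cost <= 0 and d_qaly >= 0 and (d_cost < 0 or d_qaly > 0):
        dominance = Dominance.INTERVENTION_DOMINANT
    elif d_cost >= 0 and d_qaly <= 0 and (d_cost > 0 or d_qaly < 0):
        dominance = Dominance.INTERVENTION_DOMINATED

    icer_q = d_cost / d_qaly if (dominance is Dominance.NONE and d_qaly != 0) else None
    icer_l = d_cost / d_ly if (dominance is Dominance.NONE and d_ly != 0) else None
    return CEAResult(delta_cost=d_cost, delta_qaly=d_qaly, delta_ly=d_ly,
                     icer_per_qaly=icer_q, icer_per_ly=icer_l,
                     dominance=dominance)


def nmb(result: CEAResult, wtp: float) -> float:
    """Incremental net monetary benefit: wtp × ΔQALY − ΔC (positive ⇒ adopt)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * result.delta_qaly - result.delta_cost


@dataclass(frozen=True)
class ScenarioResult:
    intervention: ArmResult
    comparator: ArmResult
    cea: CEAResult


def evaluate(scenario: Scenario,
             traces: Optional[Tuple[CohortTrace, CohortTrace]] = None
             ) -> ScenarioResult:
    """Run the full pipeline for one scenario.

    ``traces`` (intervention, comparator) may be supplied to re-cost
    previously computed occupancies — the sensitivity module exploits the
    fact that survival parameters are not varied to skip re-simulation.
    """
    if traces is None:
        traces = (run_cohort(scenario.intervention, scenario.settings),
                  run_cohort(scenario.comparator, scenario.settings))
    results = {}
    for role, trace in zip(("intervention", "comparator"), traces):
        costs = cycle_costs(scenario, role, trace)
        results[role] = accumulate(trace, costs, scenario.utilities, role,
                                   scenario.settings)
    return ScenarioResult(
        intervention=results["intervention"],
        comparator=results["comparator"],
        cea=compare(results["intervention"], results["comparator"]),
    )
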