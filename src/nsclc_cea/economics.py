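"""Cost accrual: turning a cohort trace into per-cycle dollar flows.

Conventions (all configurable fields live on the scenario):

* active-treatment drug and administration costs accrue on PFS occupancy
  while the arm's treatment schedule is active;
* imaging (CT) accrues on PFS occupancy at the 6-week rate, and on PD
  occupancy prorated to the 9-week post-progression surveillance interval
  (cost × 6/9 per 6-week cycle);
* laboratory costs accrue on both alive states;
* per-cycle subsequent therapies accrue on PD occupancy weighted by uptake
  proportion; one-time items (radiotherapy, priced per course) are charged
  on the newly-progressing flow;
* the adverse-event burden — Σ incidence × management cost per event — is a
  one-time charge at model entry.

The Calvert/Cockcroft-Gault and body-surface-area dose calculators are
audit helpers used to sanity-check listed per-cycle prices; base-case
costing uses the listed prices directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np

from .markov import CohortTrace
from .parameters import AEItem, ArmSpec, ModelSettings, Scenario

__all__ = [
    "CostBreakdown",
    "ae_burden",
    "cockcroft_gault",
    "carboplatin_dose",
    "bsa_dose",
    "cycle_costs",
]


@dataclass(frozen=True)
class CostBreakdown:
    """Undiscounted per-cycle cost flows (USD) plus one-time charges.

    ``one_time`` entries are charged at model entry (cycle 0).  The
    ``subsequent`` vector already contains both per-cycle PD therapies and
    the entry-flow-weighted one-time items, so discounting the five vectors
    and adding ``one_time`` gives the arm's total cost.
    """

    drug: np.ndarray
    admin: np.ndarray
    imaging: np.ndarray
    lab: np.ndarray
    subsequent: np.ndarray
    one_time: Dict[str, float] = field(default_factory=dict)

    @property
    def per_cycle_total(self) -> np.ndarray:
        return self.drug + self.admin + self.imaging + self.lab + self.subsequent

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "cycle": np.arange(self.drug.size),
            "drug": self.drug,
            "admin": self.admin,
            "imaging": self.imaging,
            "lab": self.lab,
            "subsequent": self.subsequent,
        })


def ae_burden(profile: Sequence[AEItem]) -> float:
    """One-time adverse-event cost: Σ risk × unit cost over the profile."""
    return float(sum(item.risk * item.unit_cost for item in profile))


def cockcroft_gault(age: float, weight: float, serum_creatinine: float,
                    sex: str = "male") -> float:
    """Creatinine clearance (mL/min): (140-age)·weight / (72·SCr), ×0.85 female."""
    if age <= 0 or weight <= 0 or serum_creatinine <= 0:
        raise ValueError("age, weight and serum creatinine must be positive")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    crcl = (140.0 - age) * weight / (72.0 * serum_creatinine)
    return crcl * 0.85 if sex == "female" else crcl


def carboplatin_dose(target_auc: float, age: float = 65.0, weight: float = 70.0,
                     serum_creatinine: float = 1.0, sex: str = "male") -> float:
    """Calvert-formula carboplatin dose (mg): AUC × (CrCl + 25)."""
    if target_auc < 0:
        raise ValueError("target AUC must be non-negative")
    return target_auc * (cockcroft_gault(age, weight, serum_creatinine, sex) + 25.0)


def bsa_dose(dose_per_m2: float, bsa: float = 1.84) -> float:
    """Body-surface-area dose (mg): dose/m² × BSA."""
    if dose_per_m2 < 0 or bsa <= 0:
        raise ValueError("dose must be non-negative and BSA positive")
    return dose_per_m2 * bsa


def _schedule_vector(arm: ArmSpec, n: int) -> np.ndarray:
    """Per-cycle active drug cost implied by the arm's treatment schedule."""
    cost = np.zeros(n)
    for entry in arm.active_treatment_schedule:
        end = n if entry.end is None else min(entry.end, n)
        if entry.start < end:
            cost[entry.start:end] += entry.cost_per_cycle
    return cost


def cycle_costs(scenario: Scenario, arm_role: str, trace: CohortTrace) -> CostBreakdown:
    """Cost flows for one arm given its cohort trace.

    Raises if the trace length does not match the scenario settings.
    """
    settings: ModelSettings = scenario.settings
    n = settings.n_cycles
    if trace.n_cycles != n:
        raise ValueError(
            f"trace has {trace.n_cycles} cycles but settings imply {n}"
        )
    arm = scenario.arm(arm_role)
    pfs, pd_state = trace.pfs, trace.pd

    drug_sched = _schedule_vector(arm, n)
    on_treatment = drug_sched > 0
    if settings.apply_discontinuation and arm.discontinuation is not None:
        drug_sched = drug_sched * (1.0 - arm.discontinuation)
    drug = drug_sched * pfs
    admin = scenario.admin_cost_per_cycle * pfs * on_treatment

    ct = scenario.ct_cost_per_cycle
    imaging = ct * pfs + ct * (6.0 / 9.0) * pd_state
    lab = scenario.lab_cost_per_cycle * (pfs + pd_state)

    subsequent = np.zeros(n)
    if settings.subsequent_cap_cycles is not None:
        cap_mask = np.arange(n) < settings.subsequent_cap_cycles
    else:
        cap_mask = np.ones(n, dtype=bool)
    for mix in arm.subsequent_mix:
        if mix.accrual == "per_cycle":
            subsequent += mix.proportion * mix.cost_per_cycle * pd_state * cap_mask
        else:
            subsequent += mix.proportion * mix.cost_per_cycle * trace.entered_pd

    one_time = {"ae_burden": ae_burden(arm.ae_profile)}
    return CostBreakdown(drug=drug, admin=admin, imaging=imaging, lab=lab,
                         subsequent=subsequent, one_time=one_time)
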