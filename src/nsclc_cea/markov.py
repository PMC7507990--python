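"""Markov cohort engine: three states (PFS, PD, dead), 6-week cycles.

Per-cycle transition probabilities come from the two fitted Weibull
endpoints of an arm.  Death strikes both alive states with the OS-curve
hazard for the current model cycle; progression removes from PFS whatever
the PFS curve loses beyond death, floored at zero.  Under this construction
the alive fraction tracks the OS curve and PFS occupancy tracks the PFS
curve (exactly so whenever the PFS hazard is at least the OS hazard) — the
partitioned-survival consistency checked by the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

from .parameters import ArmSpec, ModelSettings
from .survival import cycle_event_prob

__all__ = ["CohortTrace", "discount_factor", "transition_probs", "run_cohort"]

log = logging.getLogger(__name__)

_CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy per cycle for one arm.

    ``pfs``, ``pd``, ``dead`` are fractions of the starting cohort at each
    cycle start; ``entered_pd`` is the fraction newly progressing during the
    previous cycle (``entered_pd[0] == 0``).
    """

    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    entered_pd: np.ndarray

    @property
    def n_cycles(self) -> int:
        return int(self.pfs.size)

    @property
    def alive(self) -> np.ndarray:
        return self.pfs + self.pd

    def validate(self) -> None:
        occ = np.stack([self.pfs, self.pd, self.dead])
        if np.any(occ < -_CONSERVATION_TOL) or np.any(occ > 1 + _CONSERVATION_TOL):
            raise ValueError("occupancy outside [0, 1]")
        if np.any(np.abs(occ.sum(axis=0) - 1.0) > _CONSERVATION_TOL):
            raise ValueError("occupancy does not sum to 1")
        if np.any(np.diff(self.dead) < -_CONSERVATION_TOL):
            raise ValueError("dead fraction decreased")
        if np.any(np.diff(self.pfs) > _CONSERVATION_TOL):
            raise ValueError("PFS fraction increased")

    def to_frame(self):
        """Trace as a DataFrame with columns cycle, pfs, pd, dead, entered_pd."""
        import pandas as pd_mod

        return pd_mod.DataFrame({
            "cycle": np.arange(self.n_cycles),
            "pfs": self.pfs,
            "pd": self.pd,
            "dead": self.dead,
            "entered_pd": self.entered_pd,
        })


def discount_factor(annual_rate: float, t, cycle_length_days: float = 42.0):
    """Discount factor (1+r)**(-t * cycle_length_days / 365.25) at cycle t."""
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    t_arr = np.asarray(t, dtype=float)
    years = t_arr * cycle_length_days / 365.25
    out = (1.0 + annual_rate) ** (-years)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def transition_probs(arm: ArmSpec, t) -> Tuple[Union[float, np.ndarray],
                                               Union[float, np.ndarray]]:
    """(probability of leaving PFS, probability of dying) during cycle t."""
    return cycle_event_prob(arm.pfs, t), cycle_event_prob(arm.os, t)


def run_cohort(arm: ArmSpec, settings: ModelSettings) -> CohortTrace:
    """Propagate a unit cohort from PFS through PD to death over the horizon.

    Update rule per cycle, applied to the cycle-start occupancy:

    * from PFS: death takes the OS-curve hazard ``p_die``; progression takes
      ``max(0, p_leave_pfs - p_die)``;
    * from PD: death takes ``p_die``.

    Cycles where the PFS curve loses mass more slowly than the OS curve
    (``p_leave_pfs < p_die``) are floored — logged at debug level, not fatal.
    """
    n = settings.n_cycles
    t = np.arange(n, dtype=float)
    p_leave = np.asarray(cycle_event_prob(arm.pfs, t))
    p_die = np.asarray(cycle_event_prob(arm.os, t))
    floored = p_leave < p_die
    if np.any(floored):
        log.debug("arm %s: PFS-exit < OS hazard at %d of %d cycles (floored)",
                  arm.name, int(floored.sum()), n)
    p_prog = np.maximum(0.0, p_leave - p_die)

    pfs = np.empty(n)
    pd_state = np.empty(n)
    dead = np.empty(n)
    entered = np.zeros(n)
    pfs[0], pd_state[0], dead[0] = 1.0, 0.0, 0.0
    for k in range(n - 1):
        new_pd = pfs[k] * p_prog[k]
        pfs[k + 1] = pfs[k] * (1.0 - p_die[k] - p_prog[k])
        pd_state[k + 1] = pd_state[k] * (1.0 - p_die[k]) + new_pd
        dead[k + 1] = dead[k] + (pfs[k] + pd_state[k]) * p_die[k]
        entered[k + 1] = new_pd

    trace = CohortTrace(pfs=pfs, pd=pd_state, dead=dead, entered_pd=entered)
    trace.validate()
    return trace
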