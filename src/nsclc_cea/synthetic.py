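"""Synthetic inputs with the statistical structure the pipeline assumes.

The curve-fitting stage consumes digitized Kaplan-Meier coordinates.  This
module simulates that input from a *known* Weibull event-time process —
inverse-CDF event times for ``n_patients``, administrative censoring at a
fixed cycle, product-limit estimation on a reading grid, and optional small
additive "digitization" noise with isotonic repair — so parameter-recovery
and end-to-end behaviour are testable without any external data.  It also
jitters bundled scenarios within their published ranges to stress-test the
economic pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .parameters import Scenario, WeibullParams, builtin_scenario, get_path, set_path
from .survival import KMPointSeries

__all__ = ["SimConfig", "simulate_km", "weibull_times", "make_test_scenario"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration for one simulated digitized KM series.

    ``digitization_noise_sd`` is additive noise on the survival fractions
    (default 0.005, i.e. half a percentage point of survival), clipped and
    monotonicity-repaired afterwards; it must stay below 0.05.
    """

    true_params: WeibullParams
    n_patients: int
    admin_censor_cycle: float
    grid: np.ndarray
    seed: int = 0
    digitization_noise_sd: float = 0.005

    def __post_init__(self):
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if self.admin_censor_cycle <= 0:
            raise ValueError("censoring time must be positive")
        if not (0 <= self.digitization_noise_sd < 0.05):
            raise ValueError("digitization noise SD must lie in [0, 0.05)")
        if np.any(self.grid < 0) or np.any(self.grid > self.admin_censor_cycle):
            raise ValueError("grid must lie within [0, admin_censor_cycle]")
        if self.grid.size and np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid times must be strictly increasing")


def weibull_times(params: WeibullParams, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF Weibull event times (cycles): (-ln U / scale)**(1/shape)."""
    u = rng.uniform(size=n)
    return (-np.log(u) / params.scale) ** (1.0 / params.shape)


def simulate_km(config: SimConfig) -> KMPointSeries:
    """Simulate a pseudo-digitized KM point series from a known Weibull.

    Event times are drawn by inverse CDF, administratively censored, and
    summarised by the product-limit estimator evaluated on the reading
    grid.  Optional digitization noise is added and repaired to keep the
    series a valid survival curve (non-increasing, within (0, 1]).
    """
    rng = np.random.default_rng(config.seed)
    times = weibull_times(config.true_params, config.n_patients, rng)
    observed = np.minimum(times, config.admin_censor_cycle)
    events = times <= config.admin_censor_cycle
    if not np.any(events):
        raise ValueError("no events before censoring; nothing to estimate")

    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(observed, event_observed=events)
    s = km.survival_function_at_times(config.grid).to_numpy(dtype=float)

    # at-risk counts at each grid time
    n_at_risk = np.array([(observed >= g).sum() for g in config.grid], dtype=float)

    if config.digitization_noise_sd > 0:
        s = s + rng.normal(0.0, config.digitization_noise_sd, size=s.shape)
        if config.grid.size and config.grid[0] == 0:
            s[0] = 1.0
        s = np.minimum.accumulate(np.clip(s, 1e-6, 1.0))

    keep = s > 0
    return KMPointSeries(times=config.grid[keep], survival=s[keep],
                         n_at_risk=n_at_risk[keep])


def make_test_scenario(population: str = "pdl1_ge50", perturb_seed: int = 0,
                       jitter: float = 1.0) -> Scenario:
    """A bundled scenario with inputs jittered within their published ranges.

    Each parameter carrying a sensitivity range is redrawn uniformly from
    the interval ``baseline ± jitter × (range half-width)``, clipped to the
    range, so the result always passes validation.  ``jitter=0`` returns
    the fixture unchanged.
    """
    if not (0 <= jitter <= 1):
        raise ValueError("jitter must lie in [0, 1]")
    scenario = builtin_scenario(population)
    if jitter == 0:
        return scenario
    rng = np.random.default_rng(perturb_seed)
    for path, bounds in scenario.sa_ranges.items():
        base = get_path(scenario, path)
        lo = max(bounds.min, base - jitter * (base - bounds.min))
        hi = min(bounds.max, base + jitter * (bounds.max - base))
        set_path(scenario, path, float(rng.uniform(lo, hi)))
    return scenario
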