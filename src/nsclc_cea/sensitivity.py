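"""Sensitivity analyses: one-way (tornado), probabilistic (PSA + CEAC),
and threshold pricing.

One-way analysis reruns the full pipeline at each parameter's range bounds
with everything else at baseline.  The probabilistic analysis draws every
parameter that carries a distribution family independently — beta for
quantities bounded in [0, 1] (utilities, adverse-event risks), gamma for
non-negative costs — with moments matched to (baseline mean, range-derived
SD).  Ranges are treated as 95% intervals by default (SD = range/3.92).

Survival (Weibull) parameters carry no published range and are therefore
held fixed in both analyses; when a user-supplied scenario does vary them,
the engine detects it and re-simulates the traces per evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cea import CEAResult, ScenarioResult, evaluate, nmb
from .markov import run_cohort
from .parameters import SARange, Scenario, get_path, set_path

__all__ = [
    "TornadoEntry",
    "DistSpec",
    "PSASample",
    "CEACCurve",
    "dist_from_range",
    "one_way",
    "tornado",
    "run_psa",
    "ceac",
    "threshold_price",
]


def _touches_survival(path: str) -> bool:
    return ".os." in path or ".pfs." in path


def _base_traces(scenario: Scenario):
    return (run_cohort(scenario.intervention, scenario.settings),
            run_cohort(scenario.comparator, scenario.settings))


@dataclass(frozen=True)
class TornadoEntry:
    parameter_path: str
    low: float
    high: float
    icer_at_min: Optional[float]
    icer_at_max: Optional[float]
    span: float


@dataclass(frozen=True)
class DistSpec:
    """A beta or gamma distribution parameterised by method of moments.

    A degenerate range collapses to an exact point mass (``point`` set),
    so an all-degenerate probabilistic analysis reproduces the
    deterministic base case bit for bit.
    """

    family: str
    a: float  # beta α / gamma shape
    b: float  # beta β / gamma rate
    point: Optional[float] = None

    @property
    def mean(self) -> float:
        if self.point is not None:
            return self.point
        return self.a / (self.a + self.b) if self.family == "beta" else self.a / self.b

    def sample(self, rng: np.random.Generator, size=None):
        if self.point is not None:
            return self.point if size is None else np.full(size, self.point)
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=size)
        return rng.gamma(self.a, 1.0 / self.b, size=size)


@dataclass(frozen=True)
class PSASample:
    draw_index: int
    values: Dict[str, float]
    cea: CEAResult


@dataclass(frozen=True)
class CEACCurve:
    wtp_grid: np.ndarray
    prob_ce: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"wtp": self.wtp_grid, "prob_ce": self.prob_ce})


def dist_from_range(mean: float, lo: float, hi: float, family: str,
                    sd_divisor: float = 3.92) -> DistSpec:
    """Method-of-moments beta/gamma from (mean, range), SD = range/divisor.

    A degenerate range (lo == hi) yields an exact point mass at the mean.
    """
    if not (lo <= mean <= hi):
        raise ValueError(f"mean {mean} outside range [{lo}, {hi}]")
    sd = (hi - lo) / sd_divisor
    if family == "beta":
        if not (0 < mean < 1):
            raise ValueError("beta requires mean strictly inside (0, 1)")
        if sd == 0:
            return DistSpec("beta", a=np.nan, b=np.nan, point=mean)
        nu = mean * (1 - mean) / sd ** 2 - 1
        if nu <= 0:
            raise ValueError("range too wide for a beta with this mean")
        return DistSpec("beta", a=mean * nu, b=(1 - mean) * nu)
    if family == "gamma":
        if mean <= 0:
            raise ValueError("gamma requires a positive mean")
        if sd == 0:
            return DistSpec("gamma", a=np.nan, b=np.nan, point=mean)
        return DistSpec("gamma", a=mean ** 2 / sd ** 2, b=mean / sd ** 2)
    raise ValueError(f"unknown distribution family {family!r}")


def one_way(scenario: Scenario, parameter_path: str,
            bounds: Optional[Tuple[float, float]] = None) -> TornadoEntry:
    """ICER at the lower and upper bound of one parameter, all else baseline."""
    if bounds is None:
        if parameter_path not in scenario.sa_ranges:
            raise KeyError(f"no sa_range for {parameter_path!r}")
        rng_spec = scenario.sa_ranges[parameter_path]
        bounds = (rng_spec.min, rng_spec.max)
    lo, hi = bounds
    base_value = get_path(scenario, parameter_path)
    reuse = None if _touches_survival(parameter_path) else _base_traces(scenario)

    icers = []
    work = scenario.model_copy(deep=True)
    try:
        for value in (lo, hi):
            set_path(work, parameter_path, value)
            res = evaluate(work, traces=None if reuse is None else reuse)
            icers.append(res.cea.icer_per_qaly)
    finally:
        set_path(work, parameter_path, base_value)
    span = (abs(icers[1] - icers[0])
            if icers[0] is not None and icers[1] is not None else float("nan"))
    return TornadoEntry(parameter_path=parameter_path, low=lo, high=hi,
                        icer_at_min=icers[0], icer_at_max=icers[1], span=span)


def tornado(scenario: Scenario) -> List[TornadoEntry]:
    """All one-way entries, sorted by ICER span, largest first."""
    if not scenario.sa_ranges:
        raise ValueError("scenario defines no sensitivity ranges")
    entries = [one_way(scenario, path) for path in scenario.sa_ranges]
    return sorted(entries, key=lambda e: (np.isnan(e.span), -e.span))


def run_psa(scenario: Scenario, n_draws: int = 1000, seed: int = 0) -> List[PSASample]:
    """Monte-Carlo parameter uncertainty propagation.

    Draws each distribution-carrying parameter independently, reruns the
    pipeline per draw, and returns one :class:`PSASample` per draw.
    Reproducible for a given seed; parameters are drawn in the scenario's
    declaration order.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    paths = [p for p, r in scenario.sa_ranges.items() if r.family is not None]
    dists = {
        p: dist_from_range(get_path(scenario, p), scenario.sa_ranges[p].min,
                           scenario.sa_ranges[p].max, scenario.sa_ranges[p].family,
                           scenario.settings.range_sd_divisor)
        for p in paths
    }
    survival_varied = any(_touches_survival(p) for p in paths)
    reuse = None if survival_varied else _base_traces(scenario)

    rng = np.random.default_rng(seed)
    work = scenario.model_copy(deep=True)
    samples: List[PSASample] = []
    for i in range(n_draws):
        values = {}
        for p in paths:
            v = float(dists[p].sample(rng))
            values[p] = v
            set_path(work, p, v)
        res = evaluate(work, traces=reuse)
        samples.append(PSASample(draw_index=i, values=values, cea=res.cea))
    return samples


def ceac(samples: Sequence[PSASample], wtp_grid: Sequence[float]) -> CEACCurve:
    """Cost-effectiveness acceptability: P(NMB > 0) at each WTP value."""
    if len(samples) == 0:
        raise ValueError("no PSA samples")
    grid = np.asarray(list(wtp_grid), dtype=float)
    d_cost = np.array([s.cea.delta_cost for s in samples])
    d_qaly = np.array([s.cea.delta_qaly for s in samples])
    prob = np.array([
        float(np.mean(w * d_qaly - d_cost > 0)) for w in grid
    ])
    return CEACCurve(wtp_grid=grid, prob_ce=prob)


def threshold_price(scenario: Scenario, cost_field: str = "nivolumab",
                    wtp: Optional[float] = None,
                    tol: float = 1e-3) -> Optional[float]:
    """Smallest fractional price cut making the intervention cost-effective.

    Scales ``drug_prices[cost_field]`` by (1−r) and bisects for the least
    r ∈ [0, 1] with non-negative incremental net monetary benefit at the
    willingness-to-pay threshold.  Returns 0.0 if already cost-effective,
    None if unattainable even at a 100% price cut.
    """
    if cost_field not in scenario.drug_prices:
        raise KeyError(f"{cost_field!r} is not a drug-price component")
    if wtp is None:
        wtp = scenario.settings.wtp
    base_price = scenario.drug_prices[cost_field]
    reuse = _base_traces(scenario)
    work = scenario.model_copy(deep=True)

    def nmb_at(r: float) -> float:
        set_path(work, f"drug_prices.{cost_field}", base_price * (1.0 - r))
        return nmb(evaluate(work, traces=reuse).cea, wtp)

    if nmb_at(0.0) >= 0:
        return 0.0
    if nmb_at(1.0) < 0:
        return None
    lo, hi = 0.0, 1.0  # nmb_at(lo) < 0 <= nmb_at(hi); NMB increasing in r
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if nmb_at(mid) >= 0:
            hi = mid
        else:
            lo = mid
    return hi
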