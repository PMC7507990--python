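"""Weibull survival mathematics for the extrapolation stage.

The model extrapolates progression-free and overall survival with the
two-parameter Weibull ``S(t) = exp(-scale * t**shape)`` fitted to digitized
Kaplan-Meier coordinates.  Time is measured in 6-week model cycles
throughout; :func:`scale_to_cycles` converts parameters fitted on another
time unit.

Fitting uses the complementary-log-log linearisation: for Weibull survival,
``log(-log S(t)) = log(scale) + shape * log(t)``, so ordinary least squares
of the transformed survival fractions on log time recovers both parameters.
When numbers at risk are available, interval event counts provide weights
(a reduced form of the Hoyle-Henley patient-count reconstruction; full
at-risk-table reconstruction is not implemented because digitized series
rarely carry one).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import integrate

from .parameters import WeibullParams

__all__ = [
    "KMPointSeries",
    "FitResult",
    "weibull_survival",
    "cycle_event_prob",
    "rmst",
    "weibull_mean",
    "fit_weibull",
    "scale_to_cycles",
    "read_km",
    "write_km",
]


class FitError(ValueError):
    """Raised when a Kaplan-Meier series cannot support a Weibull fit."""


@dataclass(frozen=True)
class KMPointSeries:
    """A digitized Kaplan-Meier curve: (time, survival) points in cycles.

    ``n_at_risk``, when present, aligns with ``times`` and enables
    event-count weighting in :func:`fit_weibull`.
    """

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: Optional[np.ndarray] = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("times and survival must be equal-length 1-D arrays")
        if np.any(t < 0):
            raise ValueError("negative time in KM series")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing (no ties)")
        if np.any(s <= 0) or np.any(s > 1):
            raise ValueError("survival fractions must lie in (0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival fractions must be non-increasing")
        if t.size and t[0] == 0 and not np.isclose(s[0], 1.0):
            raise ValueError("S(0) must be 1 when t=0 is present")
        if self.n_at_risk is not None:
            n = np.asarray(self.n_at_risk, dtype=float)
            object.__setattr__(self, "n_at_risk", n)
            if n.shape != t.shape:
                raise ValueError("n_at_risk must align with times")
            if np.any(n < 0):
                raise ValueError("negative n_at_risk")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class FitResult:
    """Weibull parameters recovered from a KM series.

    ``rss`` is the residual sum of squares on the complementary-log-log
    scale (the scale the regression runs on), not on the survival scale.
    """

    params: WeibullParams
    rss: float
    n_points_used: int
    method: str = "transform_ols"


def weibull_survival(params: WeibullParams, t) -> Union[float, np.ndarray]:
    """Survival fraction S(t) = exp(-scale * t**shape), t in cycles."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = np.exp(-params.scale * t_arr ** params.shape)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def cycle_event_prob(params: WeibullParams, t) -> Union[float, np.ndarray]:
    """Conditional probability of the event during cycle [t, t+1).

    Equals ``1 - S(t+1)/S(t) = 1 - exp(scale*t**shape - scale*(t+1)**shape)``;
    the discrete per-cycle hazard driving all state transitions.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("cycle index must be non-negative")
    lam, gam = params.scale, params.shape
    out = 1.0 - np.exp(lam * t_arr ** gam - lam * (t_arr + 1.0) ** gam)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def rmst(params: WeibullParams, horizon: float) -> float:
    """Restricted mean survival time: integral of S on [0, horizon] cycles."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    value, _ = integrate.quad(
        lambda u: float(weibull_survival(params, u)),
        0.0, horizon, epsrel=1e-10, epsabs=1e-12, limit=200,
    )
    return value


def weibull_mean(params: WeibullParams) -> float:
    """Closed-form mean: scale**(-1/shape) * Gamma(1 + 1/shape), in cycles."""
    from scipy.special import gamma as gamma_fn

    return params.scale ** (-1.0 / params.shape) * gamma_fn(1.0 + 1.0 / params.shape)


def scale_to_cycles(shape: float, scale: float, time_unit_days: float,
                    cycle_length_days: float = 42.0) -> WeibullParams:
    """Re-express a Weibull fitted on another time unit in model cycles.

    If S(t) = exp(-scale * t**shape) with t in units of ``time_unit_days``,
    then in cycle units the scale becomes
    ``scale * (cycle_length_days / time_unit_days)**shape``.
    """
    factor = (cycle_length_days / time_unit_days) ** shape
    return WeibullParams(shape=shape, scale=scale * factor)


def fit_weibull(series: KMPointSeries, method: str = "transform_ols") -> FitResult:
    """Fit Weibull parameters to digitized KM coordinates.

    ``transform_ols`` regresses log(-log S) on log t by ordinary least
    squares.  ``interval_weighted`` runs the same regression weighted by the
    number of events estimated to fall in each inter-point interval from
    ``n_at_risk`` (points without at-risk data fall back to unit weight).
    Points with S = 1 (transform undefined) or t = 0 are excluded.
    """
    if method not in ("transform_ols", "interval_weighted"):
        raise ValueError(f"unknown fit method {method!r}")
    t = series.times
    s = series.survival
    usable = (t > 0) & (s < 1.0) & (s > 0)
    if int(usable.sum()) < 3:
        raise FitError(
            f"need at least 3 usable points with 0 < S < 1 and t > 0, "
            f"got {int(usable.sum())}"
        )
    x = np.log(t[usable])
    y = np.log(-np.log(s[usable]))

    weights = np.ones_like(x)
    if method == "interval_weighted" and series.n_at_risk is not None:
        n = series.n_at_risk
        # Events in the interval ending at each point: drop in survival times
        # the entering at-risk count; a crude reconstruction adequate for
        # weighting.
        s_prev = np.concatenate([[1.0], s[:-1]])
        n_prev = np.concatenate([[n[0]], n[:-1]])
        events = np.maximum((s_prev - s) / np.maximum(s_prev, 1e-12), 0.0) * n_prev
        w = events[usable]
        if np.all(w <= 0):
            raise FitError("interval_weighted: no events implied by n_at_risk")
        weights = np.maximum(w, 1e-9)

    import statsmodels.api as sm

    model = sm.WLS(y, sm.add_constant(x), weights=weights)
    res = model.fit()
    intercept, slope = res.params
    if slope <= 0:
        raise FitError("non-positive fitted shape; series is not Weibull-like")
    params = WeibullParams(shape=float(slope), scale=float(np.exp(intercept)))
    rss = float(np.sum(weights * res.resid ** 2))
    return FitResult(params=params, rss=rss, n_points_used=int(usable.sum()),
                     method=method)


# ---------------------------------------------------------------------------
# delimited text I/O (time, survival[, n_at_risk]); header optional
# ---------------------------------------------------------------------------

def read_km(path: Union[str, Path]) -> KMPointSeries:
    """Read a KM point series from 2-3 column delimited text."""
    import pandas as pd

    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0] if path.read_text().strip() else ""
    has_header = any(c.isalpha() for c in first)
    df = pd.read_csv(path, sep=None, engine="python",
                     header=0 if has_header else None)
    if df.shape[1] not in (2, 3):
        raise ValueError(f"{path}: expected 2 or 3 columns, got {df.shape[1]}")
    cols = list(df.columns)
    n_at_risk = df[cols[2]].to_numpy(float) if df.shape[1] == 3 else None
    return KMPointSeries(times=df[cols[0]].to_numpy(float),
                         survival=df[cols[1]].to_numpy(float),
                         n_at_risk=n_at_risk)


def write_km(series: KMPointSeries, path: Union[str, Path]) -> Path:
    import pandas as pd

    data = {"time": series.times, "survival": series.survival}
    if series.n_at_risk is not None:
        data["n_at_risk"] = series.n_at_risk
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
    return Path(path)
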