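"""Trajectory-level estimators for the extinction/persistence theory.

The threshold results are statements about path functionals: the running
time average <f>(t) = (1/t) * integral_0^t f(s) ds, the correction term
phi(t) that links <x> and <y>, the exponential growth rate of ln y(t), and
whether y(t) stays below a tolerance until the end of the horizon.  This
module turns a simulated :class:`~edacircuit.model.Trajectory` into those
quantities so the closed-form thresholds can be tested empirically.

Quadrature is left-endpoint throughout, matching the left-limit (t^-)
convention of the jump dynamics; the difference from the trapezoid rule is
O(dt) and irrelevant at the step sizes used here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict

import numpy as np

from .model import (
    DerivedCoefficients,
    RateConstants,
    Trajectory,
    ValidationError,
)

__all__ = [
    "ObservableSeries",
    "LogGrowthEstimate",
    "time_average_series",
    "phi_series",
    "mean_x_relation_residual",
    "log_growth_estimate",
    "detect_extinction",
    "tail_mean_y",
]

#: default extinction tolerance as a fraction of the trajectory's peak y
DEFAULT_EXTINCTION_TOL_FRACTION = 1e-6
#: default fraction of the horizon used for tail statistics
DEFAULT_TAIL_FRACTION = 0.5


@dataclass
class ObservableSeries:
    """A named time series derived from a trajectory (aligned arrays)."""

    times: np.ndarray
    values: np.ndarray
    definition: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError("ObservableSeries arrays must be aligned")


def _resolve_observable(
    traj: Trajectory, observable: str | Callable[[np.ndarray, np.ndarray], np.ndarray]
) -> tuple[np.ndarray, str]:
    x, y = traj.x, traj.y
    if callable(observable):
        return np.asarray(observable(x, y), dtype=float), getattr(
            observable, "__name__", "custom"
        )
    named: Dict[str, np.ndarray] = {"x": x, "y": y, "x*y": x * y, "x^2": x * x}
    if observable not in named:
        raise ValidationError(
            f"unknown observable {observable!r}; use one of {sorted(named)} "
            "or a callable f(x, y)"
        )
    return named[observable], observable


def time_average_series(
    traj: Trajectory,
    observable: str | Callable[[np.ndarray, np.ndarray], np.ndarray] = "y",
) -> ObservableSeries:
    """Running time average <f>(t_n) by left-endpoint quadrature.

    <f>(t_n) = (1/t_n) * sum_{i<n} f(t_i) * (t_{i+1} - t_i).  Undefined at
    t = 0, so the series starts at the first grid point after 0.
    """
    if len(traj.times) < 2:
        raise ValidationError("time_average_series needs at least one step")
    f, tag = _resolve_observable(traj, observable)
    dt = np.diff(traj.times)
    avg = np.cumsum(f[:-1] * dt) / traj.times[1:]
    return ObservableSeries(times=traj.times[1:], values=avg, definition=f"mean_{tag}")


def phi_series(
    traj: Trajectory,
    coeffs: DerivedCoefficients,
    rates: RateConstants,
) -> ObservableSeries:
    """The correction term phi(t) relating <x> and <y>.

    phi(t) = -[(x(t)-x(0))/t + (y(t)-y(0))/t] / ((2*k_minus1-k2) * <y>(t)).

    For bounded trajectories with <y> bounded away from 0 the numerator is
    O(1/t), so phi(t) -> 0; its decay is the empirical signature of the
    mean-balance relation used in the extinction proofs.  Points where
    <y> = 0 are emitted as NaN rather than raising.
    """
    denom_rate = 2.0 * rates.k_minus1 - rates.k2
    if denom_rate == 0.0:
        raise ValidationError("phi_series requires 2*k_minus1 != k2")
    mean_y = time_average_series(traj, "y")
    t = mean_y.times
    x, y = traj.x, traj.y
    num = (x[1:] - x[0]) / t + (y[1:] - y[0]) / t
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mean_y.values > 0.0, -num / (denom_rate * mean_y.values), np.nan)
    return ObservableSeries(times=t, values=phi, definition="phi")


def mean_x_relation_residual(
    traj: Trajectory,
    coeffs: DerivedCoefficients,
    rates: RateConstants,
) -> ObservableSeries:
    """Residual of the mean-balance relation
    <x>(t) = K - (k2/(2*k_minus1-k2)) * <y>(t) + phi(t).

    The relation's derivation replaces <x*y>/<y> by <x>, which is exact only
    for uncorrelated paths, so this residual is a diagnostic of that gap and
    must never be used as a correctness assertion.
    """
    denom_rate = 2.0 * rates.k_minus1 - rates.k2
    mean_x = time_average_series(traj, "x")
    mean_y = time_average_series(traj, "y")
    phi = phi_series(traj, coeffs, rates)
    predicted = coeffs.K - (rates.k2 / denom_rate) * mean_y.values + phi.values
    return ObservableSeries(
        times=mean_x.times,
        values=mean_x.values - predicted,
        definition="mean_x_relation_residual",
    )


@dataclass
class LogGrowthEstimate:
    """Two estimators of the exponential growth rate of y(t).

    ``endpoint`` is ln y(T)/T at the end of the usable (positive-y) range;
    ``tail_slope`` is the least-squares slope of ln y versus t over the last
    ``tail_fraction`` of that range and is the preferred estimator for
    comparison against the closed-form growth bounds.  ``truncated`` flags
    that y reached 0 before the end of the horizon.
    """

    endpoint: float
    tail_slope: float
    truncated: bool
    n_points: int


def log_growth_estimate(
    traj: Trajectory, tail_fraction: float = DEFAULT_TAIL_FRACTION
) -> LogGrowthEstimate:
    """Estimate the asymptotic rate of ln y(t)/t from a trajectory.

    Uses the segment before the first y <= 0 (flagged as truncated when that
    happens before the horizon end); raises if fewer than 10 usable points
    remain.
    """
    if not 0.0 < tail_fraction <= 1.0:
        raise ValidationError(f"tail_fraction must be in (0, 1], got {tail_fraction!r}")
    y = traj.y
    t = traj.times
    nonpos = np.nonzero(y <= 0.0)[0]
    end = int(nonpos[0]) if len(nonpos) else len(y)
    truncated = end < len(y)
    # skip t = 0 where ln y / t is undefined
    usable = slice(1, end)
    tu, yu = t[usable], y[usable]
    if len(tu) < 10:
        raise ValidationError(
            f"log_growth_estimate needs >= 10 usable points with y > 0, got {len(tu)}"
        )
    lny = np.log(yu)
    endpoint = lny[-1] / tu[-1]
    t_cut = tu[-1] - tail_fraction * (tu[-1] - tu[0])
    tail = tu >= t_cut
    if tail.sum() < 2:
        tail = np.zeros_like(tail, dtype=bool)
        tail[-2:] = True
    slope = float(np.polyfit(tu[tail], lny[tail], 1)[0])
    return LogGrowthEstimate(
        endpoint=float(endpoint),
        tail_slope=slope,
        truncated=truncated,
        n_points=len(tu),
    )


def detect_extinction(
    traj: Trajectory, tol: float | None = None
) -> tuple[bool, float | None]:
    """Detect sustained extinction of the intermediate y.

    The trajectory is extinct iff y <= tol from some time onward through the
    end of the horizon; that first time is returned.  A transient dip below
    tol followed by recovery is not extinction.  ``tol`` defaults to
    ``1e-6 * max(y)`` (and an identically-zero path is extinct at t = 0).
    """
    y = traj.y
    if tol is None:
        peak = float(np.max(y))
        if peak == 0.0:
            return True, 0.0
        tol = DEFAULT_EXTINCTION_TOL_FRACTION * peak
    if tol <= 0.0:
        raise ValidationError(f"tol must be > 0, got {tol!r}")
    above = np.nonzero(y > tol)[0]
    if len(above) == 0:
        return True, float(traj.times[0])
    last_above = int(above[-1])
    if last_above == len(y) - 1:
        return False, None
    return True, float(traj.times[last_above + 1])


def tail_mean_y(traj: Trajectory, tail_fraction: float = DEFAULT_TAIL_FRACTION) -> float:
    """Finite-horizon proxy for liminf <y>: the minimum of the running mean
    <y>(t) over the last ``tail_fraction`` of the horizon."""
    if not 0.0 < tail_fraction <= 1.0:
        raise ValidationError(f"tail_fraction must be in (0, 1], got {tail_fraction!r}")
    mean_y = time_average_series(traj, "y")
    t = mean_y.times
    t_cut = t[-1] - tail_fraction * (t[-1] - t[0])
    tail = t >= t_cut
    return float(np.min(mean_y.values[tail]))
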