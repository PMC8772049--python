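"""Deterministic kinetics of the entropy-driven amplifier (EDA) circuit.

The EDA circuit is a catalytic DNA strand-displacement network: a catalyst
strand reversibly displaces the blocking strand of a Spine-ThTSignal-Block
substrate (rates ``k1`` / ``k_minus1``), and a fuel strand then irreversibly
displaces the ThT-binding signal strand while regenerating the catalyst
(rate ``k2``).  Labelling the species

    x  Spine-ThTSignal-Block (substrate)
    a  Catalyst
    y  Spine-ThTSignal-Catalyst (intermediate)
    b  Block (waste)
    c  Fuel
    d  Spine-Fuel (product)
    e  ThTSignal (fluorescent reporter)

mass-action kinetics gives a seven-species polynomial ODE.  Three linear
conservation laws (substrate backbone, catalyst, fuel) reduce the system to
the two dynamic species ``(x, y)``:

    dx/dt = -a1*x + b1*y + c1x*x*y
    dy/dt =  a1*x - b2*y + c2*x*y - k2*y**2

with a1 = k1*a0, b1 = k_minus1*x0, b2 = k_minus1*x0 + k2*(c0 - x0),
c2 = k_minus1 - k1 - k2, and an xy-coefficient ``c1x`` whose sign is the one
genuinely ambiguous point of the model: the published reduced system uses
c1 = k_minus1 - k1, while substituting the conservation laws into the full
ODE yields k1 - k_minus1 = -c1.  Both conventions are supported through the
``mode`` flag (``"paper_literal"`` keeps the published sign and is the
default; ``"corrected"`` is the only mode consistent with the full model).

This module also provides the invariant-region membership test, a fixed-step
ODE integrator (RK4 / forward Euler), and the Lyapunov-function diagnostics
used to sanity-check well-posedness at desk scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence

import numpy as np

logger = logging.getLogger("edacircuit")

PAPER_LITERAL = "paper_literal"
CORRECTED = "corrected"
MODES = (PAPER_LITERAL, CORRECTED)

#: index order of the seven species in array form
FULL_SPECIES = ("x", "a", "y", "b", "c", "d", "e")


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------


class EDAError(Exception):
    """Base class for all package errors."""


class ValidationError(EDAError):
    """A parameter or configuration value violates a type invariant."""


class DegenerateParameterError(EDAError):
    """A derived quantity requires division by a vanishing combination
    (e.g. 2*k_minus1 == k2, or b2 == 0 in the threshold formulas)."""


class AdmissibilityError(EDAError):
    """A reduced state cannot be lifted to non-negative full concentrations."""


class NonFiniteStateError(EDAError):
    """Integration produced a non-finite state (overflow / blow-up)."""


class InvariantRegionError(EDAError):
    """The invariant region is empty for the supplied parameters."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateConstants:
    """Bimolecular rate constants of the two displacement reactions.

    ``k1``/``k_minus1`` are the forward/reverse rates of the catalyst
    exchange step, ``k2`` the rate of the irreversible fuel step.  All are
    per-concentration per-time and must be non-negative.  The threshold
    theory additionally divides by ``2*k_minus1 - k2``; operations that need
    that combination raise :class:`DegenerateParameterError` when it is 0.
    """

    k1: float
    k_minus1: float
    k2: float

    def __post_init__(self) -> None:
        for name in ("k1", "k_minus1", "k2"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"rates.{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class InitialConditions:
    """Initial concentrations and the starting point of the reduced state.

    ``x0``, ``a0``, ``c0`` are the loaded concentrations of substrate,
    catalyst and fuel (the other four species start at zero).  The reduced
    simulation may be started anywhere admissible; by default it starts at
    the chemically prepared state ``(x0, 0)``.
    """

    x0: float
    a0: float
    c0: float
    x_start: float | None = None
    y_start: float = 0.0

    def __post_init__(self) -> None:
        for name in ("x0", "a0", "c0"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(f"init.{name} must be finite and > 0, got {v!r}")
        if self.x_start is None:
            object.__setattr__(self, "x_start", self.x0)
        if self.x_start < 0:
            raise ValidationError(f"init.x_start must be >= 0, got {self.x_start!r}")
        if self.y_start < 0:
            raise ValidationError(f"init.y_start must be >= 0, got {self.y_start!r}")


@dataclass(frozen=True)
class DerivedCoefficients:
    """Coefficients of the reduced two-species model plus the region bound K.

    ``c1`` always stores the published value ``k_minus1 - k1``; ``c1x`` is
    the xy-coefficient actually used in the x-equation (``c1`` in
    paper_literal mode, ``-c1`` in corrected mode).  ``K`` is the
    invariant-region bound ``k2*(x0 - c0)/(2*k_minus1 - k2)``.
    """

    a1: float
    b1: float
    c1: float
    b2: float
    c2: float
    k2: float
    k_sum: float
    K: float
    mode: str
    c1x: float


def derive_coefficients(
    rates: RateConstants, init: InitialConditions, mode: str = PAPER_LITERAL
) -> DerivedCoefficients:
    """Compute the reduced-model coefficients from rates and loadings."""
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    denom = 2.0 * rates.k_minus1 - rates.k2
    if denom == 0.0:
        raise DegenerateParameterError(
            "2*k_minus1 == k2: the region bound K and the threshold formulas "
            "divide by 2*k_minus1 - k2"
        )
    c1 = rates.k_minus1 - rates.k1
    return DerivedCoefficients(
        a1=rates.k1 * init.a0,
        b1=rates.k_minus1 * init.x0,
        c1=c1,
        b2=rates.k_minus1 * init.x0 + rates.k2 * (init.c0 - init.x0),
        c2=rates.k_minus1 - rates.k1 - rates.k2,
        k2=rates.k2,
        k_sum=rates.k1 + rates.k_minus1 + rates.k2,
        K=rates.k2 * (init.x0 - init.c0) / denom,
        mode=mode,
        c1x=c1 if mode == PAPER_LITERAL else -c1,
    )


@dataclass(frozen=True)
class FullState:
    """Concentrations of all seven species."""

    x: float
    a: float
    y: float
    b: float
    c: float
    d: float
    e: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.a, self.y, self.b, self.c, self.d, self.e])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "FullState":
        return cls(*(float(v) for v in arr))


@dataclass(frozen=True)
class ReducedState:
    """Concentrations of the two dynamic species (substrate, intermediate)."""

    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class Trajectory:
    """A simulated path on a fixed time grid.

    ``states`` has one row per grid point and either 2 columns (reduced,
    ``x, y``) or 7 (full, in :data:`FULL_SPECIES` order).  ``jump_counts``
    and ``clamp_flags`` are per-step (length ``len(times) - 1``); both are
    all-zero for deterministic runs.
    """

    times: np.ndarray
    states: np.ndarray
    jump_counts: np.ndarray
    clamp_flags: np.ndarray
    seed: int | None = None
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.jump_counts = np.asarray(self.jump_counts, dtype=int)
        self.clamp_flags = np.asarray(self.clamp_flags, dtype=bool)
        n = len(self.times)
        if self.times[0] != 0.0:
            raise ValidationError("trajectory grid must start at t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("trajectory grid must be strictly increasing")
        if self.states.shape[0] != n or len(self.jump_counts) != n - 1:
            raise ValidationError(
                "trajectory arrays misaligned: need len(states) == len(times) "
                "== len(jump_counts) + 1"
            )
        if len(self.clamp_flags) != n - 1:
            raise ValidationError("clamp_flags must have one entry per step")

    @property
    def is_full(self) -> bool:
        return self.states.shape[1] == 7

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 2 if self.is_full else 1]

    @property
    def clamp_events(self) -> int:
        return int(self.clamp_flags.sum())

    def with_full(self, init: InitialConditions) -> "Trajectory":
        """Lift a reduced trajectory to all seven species via the
        conservation laws (raises :class:`AdmissibilityError`, annotated
        with the offending row, if any point is inadmissible)."""
        if self.is_full:
            return self
        full = np.empty((len(self.times), 7))
        for i, (xv, yv) in enumerate(self.states):
            try:
                full[i] = reconstruct_full(ReducedState(xv, yv), init).as_array()
            except AdmissibilityError as exc:
                raise AdmissibilityError(f"row {i} (t={self.times[i]:g}): {exc}") from exc
        return Trajectory(
            times=self.times,
            states=full,
            jump_counts=self.jump_counts,
            clamp_flags=self.clamp_flags,
            seed=self.seed,
            meta={**self.meta, "reconstructed": True},
        )


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------


def full_rhs(state: FullState | np.ndarray, rates: RateConstants) -> np.ndarray:
    """Time derivatives of the seven-species mass-action model.

    Accepts a :class:`FullState` or a length-7 array in
    :data:`FULL_SPECIES` order; returns the derivative as an array.
    """
    if isinstance(state, FullState):
        state = state.as_array()
    x, a, y, b, c = state[0], state[1], state[2], state[3], state[4]
    k1, km1, k2 = rates.k1, rates.k_minus1, rates.k2
    exch = km1 * b * y - k1 * a * x  # net rate of the reverse exchange step
    cat = k2 * c * y  # rate of the irreversible fuel step
    return np.array([exch, exch + cat, -exch - cat, -exch, -cat, cat, cat])


def reduced_rhs(
    state: ReducedState | np.ndarray, coeffs: DerivedCoefficients
) -> np.ndarray:
    """Time derivatives of the reduced (x, y) model under ``coeffs.mode``."""
    if isinstance(state, ReducedState):
        x, y = state.x, state.y
    else:
        x, y = state[0], state[1]
    dx = -coeffs.a1 * x + coeffs.b1 * y + coeffs.c1x * x * y
    dy = coeffs.a1 * x - coeffs.b2 * y + coeffs.c2 * x * y - coeffs.k2 * y * y
    return np.array([dx, dy])


# ---------------------------------------------------------------------------
# conservation laws
# ---------------------------------------------------------------------------

_ADMISSIBILITY_TOL = -1e-12


def reconstruct_full(state: ReducedState, init: InitialConditions) -> FullState:
    """Lift a reduced state to the conservation manifold.

    Uses substrate (x + y + e = x0 = x + b), catalyst (a + y = a0) and fuel
    (c + e = c0) conservation, plus d = e (both are produced one-for-one by
    the fuel step and start at 0).  Raises :class:`AdmissibilityError`
    naming the first species whose reconstructed concentration is negative
    beyond round-off.
    """
    a = init.a0 - state.y
    b = init.x0 - state.x
    e = init.x0 - state.x - state.y
    c = init.c0 - e
    values = {"x": state.x, "a": a, "y": state.y, "b": b, "c": c, "e": e}
    for name, v in values.items():
        if v < _ADMISSIBILITY_TOL:
            raise AdmissibilityError(
                f"reconstructed concentration of species {name!r} is negative "
                f"({v:.6g}); the reduced point (x={state.x:g}, y={state.y:g}) "
                "is outside the admissible region"
            )
    clip = lambda v: v if v > 0.0 else 0.0
    return FullState(
        x=clip(state.x), a=clip(a), y=clip(state.y), b=clip(b), c=clip(c),
        d=clip(e), e=clip(e),
    )


def conservation_residuals(
    traj: Trajectory, init: InitialConditions
) -> Dict[str, np.ndarray]:
    """Per-time-point absolute residuals of the conservation laws.

    Returns four named series: substrate via products (|x+y+e-x0|),
    catalyst (|a+y-a0|), fuel (|c+e-c0|) and substrate via waste
    (|x+b-x0|).  Requires a full (7-column) trajectory.
    """
    if not traj.is_full:
        raise ValidationError("conservation_residuals requires a full trajectory")
    s = traj.states
    x, a, y, b, c, e = s[:, 0], s[:, 1], s[:, 2], s[:, 3], s[:, 4], s[:, 6]
    return {
        "substrate": np.abs(x + y + e - init.x0),
        "catalyst": np.abs(a + y - init.a0),
        "fuel": np.abs(c + e - init.c0),
        "substrate_waste": np.abs(x + b - init.x0),
    }


# ---------------------------------------------------------------------------
# invariant region
# ---------------------------------------------------------------------------


def invariant_region_contains(
    state: ReducedState,
    coeffs: DerivedCoefficients,
    init: InitialConditions,
    mode: str | None = None,
) -> bool:
    """Membership in the forward-invariant region of the reduced model.

    In paper_literal mode the region is the published one,
    ``{x > 0, y > 0, x + y < K}`` with ``K = k2*(x0-c0)/(2*k_minus1-k2)``
    (requires K > 0).  In corrected mode the drift gives
    ``d(x+y)/dt = k2*y*((x0-c0) - x - y)``, so the sum bound is ``x0 - c0``
    instead; an empty region (x0 <= c0) simply contains no points.
    All inequalities are strict.
    """
    mode = coeffs.mode if mode is None else mode
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    if state.x <= 0.0 or state.y <= 0.0:
        return False
    if mode == PAPER_LITERAL:
        if coeffs.K <= 0.0:
            raise InvariantRegionError(
                f"published invariant region is empty: K = {coeffs.K:g} <= 0 "
                "(requires x0 > c0 and 2*k_minus1 > k2)"
            )
        return state.x + state.y < coeffs.K
    return state.x + state.y < init.x0 - init.c0


# ---------------------------------------------------------------------------
# fixed-step integration
# ---------------------------------------------------------------------------


def integrate_ode(
    rhs: Callable[[np.ndarray], np.ndarray],
    start: np.ndarray | Sequence[float],
    dt: float,
    t_end: float,
    method: str = "rk4",
) -> Trajectory:
    """Fixed-step integration of ``dz/dt = rhs(z)`` on the grid {0, dt, ...}.

    ``method`` is ``"rk4"`` (classical Runge-Kutta) or ``"euler"``.  The
    grid covers ``[0, t_end]`` with ``round(t_end/dt)`` steps.  Fixed
    stepping keeps runs bit-reproducible and grids aligned for time-average
    diagnostics; a non-finite state aborts with a diagnostic.
    """
    if dt <= 0:
        raise ValidationError(f"dt must be > 0, got {dt!r}")
    if t_end < dt:
        raise ValidationError(f"t_end must be >= dt, got t_end={t_end!r} dt={dt!r}")
    if method not in ("rk4", "euler"):
        raise ValidationError(f"method must be 'rk4' or 'euler', got {method!r}")
    n_steps = int(round(t_end / dt))
    z = np.asarray(start, dtype=float).copy()
    states = np.empty((n_steps + 1, z.size))
    states[0] = z
    for i in range(n_steps):
        if method == "rk4":
            k1 = rhs(z)
            k2 = rhs(z + 0.5 * dt * k1)
            k3 = rhs(z + 0.5 * dt * k2)
            k4 = rhs(z + dt * k3)
            z = z + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        else:
            z = z + dt * rhs(z)
        if not np.all(np.isfinite(z)):
            raise NonFiniteStateError(
                f"non-finite state at t = {(i + 1) * dt:g} (step {i + 1}); "
                "reduce dt or check parameters"
            )
        states[i + 1] = z
    times = np.arange(n_steps + 1) * dt
    return Trajectory(
        times=times,
        states=states,
        jump_counts=np.zeros(n_steps, dtype=int),
        clamp_flags=np.zeros(n_steps, dtype=bool),
        seed=None,
        meta={"scheme": method, "dt": dt},
    )


# ---------------------------------------------------------------------------
# Lyapunov diagnostics
# ---------------------------------------------------------------------------


def lyapunov_V(state: ReducedState | Sequence[float]) -> float:
    """The well-posedness Lyapunov function V = (x-1-ln x) + (y-1-ln y).

    Non-negative on the open positive quadrant with its global minimum 0 at
    (1, 1); it blows up at the axes and at infinity, which is what makes it
    useful for ruling out explosion and loss of positivity.
    """
    if isinstance(state, ReducedState):
        x, y = state.x, state.y
    else:
        x, y = float(state[0]), float(state[1])
    if x <= 0.0 or y <= 0.0:
        raise ValidationError(f"lyapunov_V requires x > 0 and y > 0, got ({x!r}, {y!r})")
    return (x - 1.0 - math.log(x)) + (y - 1.0 - math.log(y))


def lv_bound_C(
    coeffs: DerivedCoefficients,
    init: InitialConditions,
    rates: RateConstants,
    noise: "NoiseSpec",  # noqa: F821 - forward ref, see edacircuit.sde
) -> float:
    """Constant C bounding the generator LV of the jump-diffusion.

    C = k1*a0 + k_minus1*x0 + k2*(c0-x0) + (k1+k_minus1+k2)*K
        + sigma^2*K^2 + delta^2/(1-delta)^2 * lambda(Y)

    A finite C certifies (at desk scale) that V grows at most linearly in
    expectation, the key estimate behind global existence of positive
    solutions.  Requires the jump-size bound delta < 1.
    """
    if noise.delta >= 1.0:
        raise ValidationError(f"lv_bound_C requires delta < 1, got {noise.delta!r}")
    d = noise.delta
    return (
        rates.k1 * init.a0
        + rates.k_minus1 * init.x0
        + rates.k2 * (init.c0 - init.x0)
        + coeffs.k_sum * coeffs.K
        + noise.sigma**2 * coeffs.K**2
        + d**2 / (1.0 - d) ** 2 * noise.lambda_Y
    )
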