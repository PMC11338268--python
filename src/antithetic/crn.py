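"""Reaction-network representation and simulation.

A :class:`ReactionNetwork` is a list of reactions, each a stoichiometry
vector together with a propensity function ``lambda(x, t) >= 0``.  The
deterministic dynamics are ``xdot = sum_r s_r * lambda_r(x, t)``; the
stochastic dynamics are the corresponding Markov jump process, sampled
exactly with the Gillespie direct method.

Closed-loop controller models elsewhere in the package are plain vector
fields rather than reaction lists; the integration and steady-state
machinery therefore also accepts any object exposing ``rhs(t, x)`` and
``state_names``.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "Schedule",
    "Reaction",
    "ReactionNetwork",
    "Trajectory",
    "SteadyStateResult",
    "SimulationError",
    "ValidationError",
    "simulate_ode",
    "simulate_ssa",
    "simulate_system",
    "find_steady_state",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

# Sequestration rates up to 1e4 make closed-loop ODEs stiff; default to an
# implicit solver with tight tolerances.
DEFAULT_METHOD = "BDF"
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

# States exceeding this magnitude are treated as numerically divergent.
DIVERGENCE_BOUND = 1e9


class SimulationError(RuntimeError):
    """Raised when the integrator fails (stiffness, step underflow, ...)."""


class ValidationError(ValueError):
    """Raised on malformed inputs (negative propensity, shape mismatch, ...)."""


@dataclass(frozen=True)
class Schedule:
    """Piecewise-constant, right-continuous parameter schedule.

    ``values[i]`` holds on the half-open interval
    ``[breakpoints[i], breakpoints[i+1])``; before the first breakpoint the
    first value applies, after the last breakpoint the last value applies.
    """

    breakpoints: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.breakpoints) != len(self.values):
            raise ValidationError("breakpoints and values must have equal length")
        if len(self.breakpoints) == 0:
            raise ValidationError("schedule needs at least one breakpoint")
        if any(b >= a for a, b in zip(self.breakpoints[1:], self.breakpoints)):
            raise ValidationError("breakpoints must be strictly increasing")

    def __call__(self, t: float) -> float:
        i = bisect.bisect_right(self.breakpoints, t) - 1
        return self.values[max(i, 0)]

    @staticmethod
    def constant(value: float) -> "Schedule":
        return Schedule((0.0,), (float(value),))


def as_schedule(value) -> Schedule:
    """Coerce a scalar or Schedule to a Schedule."""
    if isinstance(value, Schedule):
        return value
    return Schedule.constant(float(value))


@dataclass(frozen=True)
class Reaction:
    stoichiometry: tuple[int, ...]
    propensity: Callable[[np.ndarray, float], float]
    name: str = ""


@dataclass
class ReactionNetwork:
    """Species, stoichiometries and propensity evaluators.

    ``signed_species`` marks species that represent signed coordinates
    (e.g. the net molecular count ``z1 - z2`` of a strong-sequestration
    limit); nonnegativity checks are skipped for those species.
    """

    species_names: list[str]
    reactions: list[Reaction]
    parameters: dict[str, float] = field(default_factory=dict)
    time_varying: dict[str, Schedule] = field(default_factory=dict)
    signed_species: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        n = len(self.species_names)
        for r in self.reactions:
            if len(r.stoichiometry) != n:
                raise ValidationError(
                    f"reaction {r.name!r}: stoichiometry length {len(r.stoichiometry)} "
                    f"!= species count {n}"
                )
            if any(int(s) != s for s in r.stoichiometry):
                raise ValidationError(f"reaction {r.name!r}: non-integer stoichiometry")

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def stoichiometry_matrix(self) -> np.ndarray:
        return np.array([r.stoichiometry for r in self.reactions], dtype=float).T

    def propensities(self, x: np.ndarray, t: float) -> np.ndarray:
        a = np.array([r.propensity(x, t) for r in self.reactions], dtype=float)
        if np.any(a < 0):
            bad = int(np.argmin(a))
            raise ValidationError(
                f"negative propensity {a[bad]:.3g} in reaction "
                f"{self.reactions[bad].name or bad} at t={t:.6g}"
            )
        return a

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        # Propensities are defined on the nonnegative orthant; the solver may
        # probe marginally negative states, so evaluate at the clipped state.
        xe = self._eval_state(x)
        return self.stoichiometry_matrix() @ self.propensities(xe, t)

    def _eval_state(self, x: np.ndarray) -> np.ndarray:
        xe = np.asarray(x, dtype=float).copy()
        for i, name in enumerate(self.species_names):
            if name not in self.signed_species:
                xe[i] = max(xe[i], 0.0)
        return xe

    def breakpoints(self) -> list[float]:
        pts: set[float] = set()
        for sched in self.time_varying.values():
            pts.update(sched.breakpoints)
        return sorted(pts)

    @property
    def state_names(self) -> list[str]:
        return self.species_names


@dataclass
class Trajectory:
    """Simulation output: times (increasing), states (time x species)."""

    times: np.ndarray
    states: np.ndarray
    species_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if self.states.shape[0] != self.times.size:
            raise ValidationError("states must have one row per time point")

    def species(self, name: str) -> np.ndarray:
        return self.states[:, self.species_names.index(name)]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def interpolate(self, t_grid: np.ndarray) -> np.ndarray:
        """Linear interpolation of every species onto ``t_grid``."""
        t_grid = np.asarray(t_grid, dtype=float)
        lo, hi = self.times[0], self.times[-1]
        if t_grid.min() < lo - 1e-12 or t_grid.max() > hi + 1e-12:
            raise ValidationError(
                f"interpolation grid [{t_grid.min():g}, {t_grid.max():g}] outside "
                f"trajectory horizon [{lo:g}, {hi:g}]"
            )
        out = np.empty((t_grid.size, self.states.shape[1]))
        for j in range(self.states.shape[1]):
            out[:, j] = np.interp(t_grid, self.times, self.states[:, j])
        return out

    def to_csv(self, path, meta_path=None) -> None:
        df = pd.DataFrame(self.states, columns=self.species_names)
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False, float_format="%.12g")
        if meta_path is not None:
            Path(meta_path).write_text(json.dumps(self.meta, indent=2, default=str))


@dataclass
class SteadyStateResult:
    state: np.ndarray
    residual: float
    status: str  # converged | diverged | max_time
    time: float = 0.0
    trajectory: Trajectory | None = None

    @property
    def converged(self) -> bool:
        return self.status == "converged"


def _segment_edges(t0: float, t1: float, breakpoints: Sequence[float]) -> list[float]:
    edges = [t0] + [b for b in breakpoints if t0 < b < t1] + [t1]
    return edges


def _integrate(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    x0: np.ndarray,
    t_span: tuple[float, float],
    *,
    t_eval: np.ndarray | None,
    rtol: float,
    atol: float,
    method: str,
    breakpoints: Sequence[float] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate, restarting at schedule breakpoints to avoid event miss."""
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 < t0:
        raise ValidationError("horizon must satisfy t_end >= t_start")
    if t1 == t0:
        return np.array([t0]), np.asarray(x0, float)[None, :]
    if t_eval is None:
        t_eval = np.linspace(t0, t1, 2001)
    t_eval = np.asarray(t_eval, dtype=float)

    times_out = [np.array([t0])]
    states_out = [np.asarray(x0, float)[None, :]]
    x = np.asarray(x0, dtype=float)
    for a, b in zip(edges := _segment_edges(t0, t1, breakpoints), edges[1:]):
        mask = (t_eval > a) & (t_eval <= b)
        seg_eval = np.unique(np.concatenate([t_eval[mask], [b]]))
        # Evaluate schedules just inside the segment (right-continuity).
        sol = solve_ivp(
            rhs, (a, b), x, method=method, t_eval=seg_eval, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise SimulationError(
                f"ODE solver failed near t={sol.t[-1] if sol.t.size else a:.6g}: "
                f"{sol.message}"
            )
        x = sol.y[:, -1]
        keep = t_eval[mask]
        if keep.size:
            idx = np.searchsorted(sol.t, keep)
            times_out.append(keep)
            states_out.append(sol.y[:, idx].T)
    times = np.concatenate(times_out)
    states = np.vstack(states_out)
    return times, states


def _clip_roundoff(states: np.ndarray, names: Sequence[str], atol: float,
                   signed: frozenset = frozenset()) -> np.ndarray:
    """Clip tiny negative round-off to zero; leave larger excursions visible."""
    out = states.copy()
    for j, name in enumerate(names):
        if name in signed:
            continue
        col = out[:, j]
        col[(col < 0) & (col >= -10 * atol)] = 0.0
    return out


def simulate_ode(
    network: ReactionNetwork,
    x0: Sequence[float],
    t_span: tuple[float, float],
    *,
    t_eval: np.ndarray | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
) -> Trajectory:
    """Deterministic solution of the reaction-rate equations.

    The output grid is dense enough (2001 points by default) that sup-norm
    metrics over the horizon can be approximated on the returned grid.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.size != network.n_species:
        raise ValidationError(
            f"x0 has {x0.size} entries, network has {network.n_species} species"
        )
    times, states = _integrate(
        network.rhs, x0, t_span,
        t_eval=t_eval, rtol=rtol, atol=atol, method=method,
        breakpoints=network.breakpoints(),
    )
    states = _clip_roundoff(states, network.species_names, atol, network.signed_species)
    return Trajectory(
        times, states, list(network.species_names),
        meta={"solver": method, "rtol": rtol, "atol": atol},
    )


def simulate_system(
    system,
    x0: Sequence[float] | None,
    t_span: tuple[float, float],
    *,
    t_eval: np.ndarray | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
) -> Trajectory:
    """Integrate any object with ``rhs(t, x)`` and ``state_names``.

    ``x0=None`` starts from the all-zero state, the package-wide default for
    closed-loop simulations.
    """
    names = list(system.state_names)
    if x0 is None:
        x0 = np.zeros(len(names))
    x0 = np.asarray(x0, dtype=float)
    if x0.size != len(names):
        raise ValidationError("x0 length does not match system state dimension")
    breakpoints = system.breakpoints() if hasattr(system, "breakpoints") else ()
    times, states = _integrate(
        system.rhs, x0, t_span,
        t_eval=t_eval, rtol=rtol, atol=atol, method=method,
        breakpoints=breakpoints,
    )
    signed = getattr(system, "signed_species", frozenset())
    states = _clip_roundoff(states, names, atol, frozenset(signed))
    return Trajectory(times, states, names,
                      meta={"solver": method, "rtol": rtol, "atol": atol})


def simulate_ssa(
    network: ReactionNetwork,
    x0: Sequence[int],
    t_max: float,
    seed: int,
    *,
    max_events: int = 10_000_000,
) -> Trajectory:
    """One exact realization of the jump process (Gillespie direct method).

    Propensities are evaluated at the current (integer) copy-number state;
    time-varying parameters are sampled at the current time, i.e. rates are
    treated as constant between consecutive events.
    """
    x0 = np.asarray(x0, dtype=float)
    if not np.allclose(x0, np.round(x0)):
        raise ValidationError("SSA initial state must be integer copy numbers")
    if x0.size != network.n_species:
        raise ValidationError("x0 length does not match species count")
    rng = np.random.default_rng(seed)
    stoich = np.array([r.stoichiometry for r in network.reactions], dtype=float)

    t = 0.0
    x = x0.copy()
    times = [0.0]
    states = [x.copy()]
    for _ in range(max_events):
        a = network.propensities(x, t)
        a_total = a.sum()
        if a_total <= 0.0:
            break
        t += rng.exponential(1.0 / a_total)
        if t > t_max:
            break
        j = rng.choice(a.size, p=a / a_total)
        x = x + stoich[j]
        times.append(t)
        states.append(x.copy())
    else:
        raise SimulationError(f"SSA exceeded {max_events} events before t={t_max}")
    times.append(t_max)
    states.append(x.copy())
    return Trajectory(
        np.array(times), np.array(states), list(network.species_names),
        meta={"solver": "gillespie-direct", "seed": seed},
    )


def find_steady_state(
    system,
    x0: Sequence[float] | None = None,
    *,
    tol_abs: float = 1e-9,
    tol_rel: float = 1e-9,
    t_max: float = 1e5,
    chunk: float = 50.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
    divergence_bound: float = DIVERGENCE_BOUND,
) -> SteadyStateResult:
    """Integrate until ``||xdot|| < tol_rel*||x|| + tol_abs``, or declare
    divergence, or give up at ``t_max``.

    Divergence fires when a state magnitude exceeds ``divergence_bound`` or
    when, at ``t_max``, the state norm has kept growing over the last 20 % of
    the horizon with a non-vanishing vector field (the signature of a missing
    closed-loop fixed point: a controller species ramping without bound).
    """
    if isinstance(system, ReactionNetwork):
        rhs = system.rhs
        names = system.species_names
        breakpoints = system.breakpoints()
    else:
        rhs = system.rhs
        names = list(system.state_names)
        breakpoints = list(system.breakpoints()) if hasattr(system, "breakpoints") else []
    if x0 is None:
        x0 = np.zeros(len(names))
    x = np.asarray(x0, dtype=float)

    t_start = max([0.0] + breakpoints)  # schedules constant beyond last breakpoint
    t = 0.0
    history: list[tuple[float, float, float]] = []  # (t, ||x||, ||xdot||)

    def residual(t_, x_):
        return float(np.linalg.norm(rhs(t_, x_)))

    r0 = residual(t, x)
    if r0 < tol_rel * np.linalg.norm(x) + tol_abs:
        return SteadyStateResult(x, r0, "converged", time=t)

    while t < t_max:
        t_next = min(t + chunk, t_max)
        _, states = _integrate(
            rhs, x, (t, t_next), t_eval=np.array([t_next]),
            rtol=rtol, atol=atol, method=method,
            breakpoints=[b for b in breakpoints if t < b < t_next],
        )
        x = states[-1]
        t = t_next
        if np.any(np.abs(x) > divergence_bound):
            return SteadyStateResult(x, residual(t, x), "diverged", time=t)
        r = residual(t, x)
        history.append((t, float(np.linalg.norm(x)), r))
        if t >= t_start and r < tol_rel * np.linalg.norm(x) + tol_abs:
            return SteadyStateResult(x, r, "converged", time=t)

    # Windowed growth test over the last 20% of the horizon.
    window = [h for h in history if h[0] >= 0.8 * t_max]
    if len(window) >= 2:
        norms = [h[1] for h in window]
        resids = [h[2] for h in window]
        growing = all(b >= a - tol_abs for a, b in zip(norms, norms[1:])) and norms[-1] > norms[0]
        sustained = resids[-1] > 0.5 * resids[0] and resids[-1] > tol_abs
        if growing and sustained:
            return SteadyStateResult(x, resids[-1], "diverged", time=t_max)
    return SteadyStateResult(x, residual(t_max, x), "max_time", time=t_max)
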