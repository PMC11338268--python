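"""Model reduction for networks with one fast sequestration reaction.

A fast-sequestration system couples an arbitrary subnetwork ``x`` to a pair
of species ``Z1, Z2`` that annihilate each other at rate ``eta``:

    xdot  = F(x, z1, z2)
    z1dot = W1(x, z1, z2) - eta*z1*z2
    z2dot = W2(x, z1, z2) - eta*z1*z2

In the strong-sequestration limit ``eta -> oo`` the pair collapses onto a
single signed coordinate ``z = z1 - z2`` whose positive and negative parts
stand in for ``z1`` and ``z2``:

    xdot = F(x, z+, z-)
    zdot = W1(x, z+, z-) - W2(x, z+, z-),    z(0) = z1(0) - z2(0)

The convergence is uniform on compact time intervals (sup norm on
``(x, z1 - z2)``) and in an L1 sense on ``(x, z1, z2)`` vs ``(x, z+, z-)``;
fixed points converge accordingly, a nonnegative fixed point of the full
system tending to ``(xbar, zbar+, zbar-)``.  This module constructs the
reduced system, measures both discrepancy metrics on simulated
trajectories, and lifts/refines fixed points between the two descriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import root

from .crn import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    Trajectory,
    ValidationError,
    _integrate,
)

__all__ = [
    "positive_negative_parts",
    "FastSequestrationSpec",
    "ReducedSpec",
    "DiscrepancyReport",
    "reduce_spec",
    "discrepancy",
    "lift_fixed_point",
    "full_fixed_point",
    "convergence_study",
]


def positive_negative_parts(z):
    """Split a signed scalar or signal into ``(z+, z-)``.

    Satisfies ``z+ - z- = z`` and ``z+ * z- = 0`` exactly.
    """
    z = np.asarray(z, dtype=float)
    zp, zn = np.maximum(z, 0.0), np.maximum(-z, 0.0)
    if zp.ndim == 0:
        return float(zp), float(zn)
    return zp, zn


@dataclass
class FastSequestrationSpec:
    """The full system: rate maps F, W1, W2 plus sequestration rate eta.

    ``F(t, x, z1, z2)`` returns the rate vector of the x-subsystem (may be
    empty), ``W1`` and ``W2`` the net production rates of Z1 and Z2
    excluding the shared sequestration term.  ``a`` and ``b`` are the
    nonnegative initial values of z1 and z2.
    """

    W1: Callable[[float, np.ndarray, float, float], float]
    W2: Callable[[float, np.ndarray, float, float], float]
    eta: float
    F: Callable[[float, np.ndarray, float, float], np.ndarray] | None = None
    x0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    a: float = 0.0
    b: float = 0.0
    x_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        if self.eta <= 0:
            raise ValidationError("sequestration rate eta must be positive")
        if self.a < 0 or self.b < 0:
            raise ValidationError("initial values a, b must be nonnegative")
        if self.x_names is None:
            self.x_names = [f"x{i+1}" for i in range(self.x0.size)]

    @property
    def n_x(self) -> int:
        return self.x0.size

    @property
    def state_names(self) -> list[str]:
        return [*self.x_names, "z1", "z2"]

    @property
    def initial_state(self) -> np.ndarray:
        return np.concatenate([self.x0, [self.a, self.b]])

    def rhs(self, t: float, s: np.ndarray) -> np.ndarray:
        x, z1, z2 = s[: self.n_x], s[-2], s[-1]
        seq = self.eta * max(z1, 0.0) * max(z2, 0.0)
        dz1 = self.W1(t, x, z1, z2) - seq
        dz2 = self.W2(t, x, z1, z2) - seq
        dx = self.F(t, x, z1, z2) if self.F is not None else np.zeros(0)
        return np.concatenate([np.atleast_1d(dx), [dz1, dz2]])

    def with_eta(self, eta: float) -> "FastSequestrationSpec":
        return FastSequestrationSpec(
            W1=self.W1, W2=self.W2, eta=eta, F=self.F,
            x0=self.x0.copy(), a=self.a, b=self.b, x_names=list(self.x_names),
        )

    def simulate(self, t_span, *, t_eval=None, rtol=DEFAULT_RTOL,
                 atol=DEFAULT_ATOL, method="BDF") -> Trajectory:
        times, states = _integrate(self.rhs, self.initial_state, t_span,
                                   t_eval=t_eval, rtol=rtol, atol=atol,
                                   method=method)
        return Trajectory(times, states, self.state_names,
                          meta={"solver": method, "eta": self.eta})


@dataclass
class ReducedSpec:
    """Strong-sequestration limit: signed coordinate z with drift W1 - W2."""

    source: FastSequestrationSpec

    @property
    def n_x(self) -> int:
        return self.source.n_x

    @property
    def state_names(self) -> list[str]:
        return [*self.source.x_names, "z"]

    @property
    def z0(self) -> float:
        return self.source.a - self.source.b

    @property
    def initial_state(self) -> np.ndarray:
        return np.concatenate([self.source.x0, [self.z0]])

    def drift(self, t: float, x: np.ndarray, z: float) -> float:
        zp, zn = positive_negative_parts(z)
        return self.source.W1(t, x, zp, zn) - self.source.W2(t, x, zp, zn)

    def rhs(self, t: float, s: np.ndarray) -> np.ndarray:
        x, z = s[: self.n_x], s[-1]
        zp, zn = positive_negative_parts(z)
        dx = self.source.F(t, x, zp, zn) if self.source.F is not None else np.zeros(0)
        return np.concatenate([np.atleast_1d(dx), [self.drift(t, x, z)]])

    @property
    def signed_species(self) -> frozenset:
        return frozenset({"z"})

    def simulate(self, t_span, *, t_eval=None, rtol=DEFAULT_RTOL,
                 atol=DEFAULT_ATOL, method="BDF") -> Trajectory:
        times, states = _integrate(self.rhs, self.initial_state, t_span,
                                   t_eval=t_eval, rtol=rtol, atol=atol,
                                   method=method)
        return Trajectory(times, states, self.state_names,
                          meta={"solver": method, "reduced": True})


def reduce_spec(spec: FastSequestrationSpec) -> ReducedSpec:
    """Construct the reduced system of a fast-sequestration specification."""
    return ReducedSpec(spec)


@dataclass
class DiscrepancyReport:
    sup_metric: float
    l1_metric: float
    T: float
    eta: float
    n_grid: int

    def __post_init__(self) -> None:
        if self.sup_metric < 0 or self.l1_metric < 0:
            raise ValidationError("discrepancy metrics must be nonnegative")


def discrepancy(
    full: Trajectory,
    reduced: Trajectory,
    T: float,
    *,
    eta: float = float("nan"),
    n_grid: int = 2001,
) -> DiscrepancyReport:
    """Distance between a full trajectory ``(x, z1, z2)`` and a reduced one
    ``(x, z)`` over ``[0, T]``.

    The sup metric compares ``(x, z1 - z2)`` with ``(x, z)`` pointwise in the
    Euclidean norm; the L1 metric integrates (trapezoidal rule) the Euclidean
    distance between ``(x, z1, z2)`` and ``(x, z+, z-)``.
    """
    if full.times[-1] < T - 1e-9 or reduced.times[-1] < T - 1e-9:
        raise ValidationError("both trajectories must cover [0, T]")
    if full.states.shape[1] != reduced.states.shape[1] + 1:
        raise ValidationError(
            "full trajectory must carry (x, z1, z2) and reduced (x, z)"
        )
    grid = np.linspace(0.0, T, n_grid)
    sf = full.interpolate(grid)
    sr = reduced.interpolate(grid)
    xf, z1, z2 = sf[:, :-2], sf[:, -2], sf[:, -1]
    xr, z = sr[:, :-1], sr[:, -1]
    zp, zn = positive_negative_parts(z)

    diff_sup = np.hstack([xf - xr, (z1 - z2 - z)[:, None]])
    sup_metric = float(np.max(np.linalg.norm(diff_sup, axis=1)))
    diff_l1 = np.hstack([xf - xr, (z1 - zp)[:, None], (z2 - zn)[:, None]])
    l1_metric = float(np.trapezoid(np.linalg.norm(diff_l1, axis=1), grid))
    return DiscrepancyReport(sup_metric, l1_metric, T, eta, n_grid)


def lift_fixed_point(
    reduced: ReducedSpec,
    x_bar: Sequence[float],
    z_bar: float,
    *,
    tol: float = 1e-6,
    t: float = 0.0,
) -> np.ndarray:
    """Map a reduced fixed point ``(xbar, zbar)`` to the candidate limit
    ``(xbar, zbar+, zbar-)`` of full-model fixed points as eta grows."""
    x_bar = np.atleast_1d(np.asarray(x_bar, dtype=float))
    s = np.concatenate([x_bar, [z_bar]])
    res = float(np.linalg.norm(reduced.rhs(t, s)))
    if res > tol:
        raise ValidationError(
            f"(x, z) is not a fixed point of the reduced system: residual {res:.3g}"
        )
    zp, zn = positive_negative_parts(z_bar)
    return np.concatenate([x_bar, [zp, zn]])


def full_fixed_point(
    spec: FastSequestrationSpec,
    start: Sequence[float],
    *,
    t: float = 0.0,
    tol: float = 1e-10,
) -> np.ndarray:
    """Refine a fixed point of the full system by root-finding.

    Start from the lifted reduced fixed point: when the reduced system has a
    unique fixed point it is the unique limit of the full-model fixed points,
    so it brackets the root for large eta.
    """
    start = np.asarray(start, dtype=float)
    sol = root(lambda s: spec.rhs(t, s), start, method="hybr", tol=tol)
    if not sol.success:
        raise ValidationError(f"full-model fixed-point search failed: {sol.message}")
    return sol.x


def convergence_study(
    spec: FastSequestrationSpec,
    eta_grid: Sequence[float],
    T: float,
    *,
    n_grid: int = 2001,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> pd.DataFrame:
    """Discrepancy metrics of the full vs reduced system across a grid of
    sequestration rates (same horizon, solver and output grid for each)."""
    eta_grid = list(eta_grid)
    if not eta_grid:
        raise ValidationError("eta grid must be nonempty")
    t_eval = np.linspace(0.0, T, n_grid)
    reduced = reduce_spec(spec)
    traj_red = reduced.simulate((0.0, T), t_eval=t_eval, rtol=rtol, atol=atol)
    rows = []
    for eta in eta_grid:
        traj_full = spec.with_eta(eta).simulate((0.0, T), t_eval=t_eval,
                                                rtol=rtol, atol=atol)
        rep = discrepancy(traj_full, traj_red, T, eta=eta, n_grid=n_grid)
        rows.append({"eta": eta, "sup_metric": rep.sup_metric,
                     "l1_metric": rep.l1_metric})
    return pd.DataFrame(rows)
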