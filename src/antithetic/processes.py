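"""Open-loop process models, steady-state input/output maps, and the
admissibility calculus.

A setpoint ``r`` is *admissible* for a process with steady-state map
``ybar = P(ubar)`` and feasible-input set ``U`` when some feasible input
supports it, i.e. ``P(ubar) = r`` for some ``ubar in U``.  Admissibility is
an algebraic property of the process and actuation mechanism alone: if a
setpoint is inadmissible, no controller of any structure can deliver it.
The same calculus yields the disturbances that preserve admissibility of a
given setpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .crn import Schedule, ValidationError, as_schedule

__all__ = [
    "Interval",
    "AffineIOMap",
    "GeneExpressionProcess",
    "UnimolecularProcess",
    "StabilityError",
    "NoSupportingInputError",
    "io_map_unimolecular",
    "supporting_input",
    "admissible_setpoints",
    "admissible_disturbances",
    "admissible_input_setpoints",
    "hurwitz_metzler_check",
    "HurwitzMetzlerVerdict",
]

_INF = float("inf")


class StabilityError(RuntimeError):
    """The steady-state map is undefined (open-loop dynamics not Hurwitz)."""


class NoSupportingInputError(ValueError):
    """No feasible input supports the requested setpoint."""


@dataclass(frozen=True)
class Interval:
    """An interval of extended reals; infinite endpoints are open.

    Finite endpoints attained by a feasible input are treated as closed.
    """

    lo: float
    hi: float
    lo_closed: bool = True
    hi_closed: bool = True

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValidationError(f"interval endpoints out of order: {self}")
        if math.isinf(self.lo):
            object.__setattr__(self, "lo_closed", False)
        if math.isinf(self.hi):
            object.__setattr__(self, "hi_closed", False)

    @staticmethod
    def empty() -> "Interval":
        iv = Interval(0.0, 0.0, False, False)
        object.__setattr__(iv, "_empty", True)
        return iv

    @property
    def is_empty(self) -> bool:
        return getattr(self, "_empty", False) or (
            self.lo == self.hi and not (self.lo_closed and self.hi_closed)
        )

    @property
    def is_singleton(self) -> bool:
        return (not self.is_empty) and self.lo == self.hi

    def contains(self, x: float) -> bool:
        if self.is_empty:
            return False
        if x < self.lo or x > self.hi:
            return False
        if x == self.lo and not self.lo_closed:
            return False
        if x == self.hi and not self.hi_closed:
            return False
        return True

    __contains__ = contains

    def intersect(self, other: "Interval") -> "Interval":
        if self.is_empty or other.is_empty:
            return Interval.empty()
        lo, lo_c = max((self.lo, not self.lo_closed), (other.lo, not other.lo_closed))
        hi, hi_c = min((self.hi, self.hi_closed), (other.hi, other.hi_closed))
        lo_c = not lo_c
        if lo > hi or (lo == hi and not (lo_c and hi_c)):
            return Interval.empty()
        return Interval(lo, hi, lo_c, hi_c)

    def clamp(self, x: float) -> float:
        return min(max(x, self.lo), self.hi)

    def image(self, f: Callable[[float], float], *, increasing: bool = True) -> "Interval":
        """Image under a strictly monotone function (endpoint mapping).

        An infinite endpoint maps to the limit of ``f`` along it: infinity
        when ``f`` is unbounded in that direction, otherwise the saturation
        value (open either way).
        """
        if self.is_empty:
            return Interval.empty()

        def ev(endpoint: float) -> float:
            if not math.isinf(endpoint):
                return f(endpoint)
            sign = 1.0 if endpoint > 0 else -1.0
            v1, v2 = f(sign * 1e9), f(sign * 1e12)
            if abs(v2 - v1) > 1e-6 * max(1.0, abs(v2)):
                return math.copysign(_INF, v2 - v1)
            return v2

        a, a_open = ev(self.lo), not self.lo_closed
        b, b_open = ev(self.hi), not self.hi_closed
        if not increasing:
            a, b = b, a
            a_open, b_open = b_open, a_open
        return Interval(a, b, not a_open, not b_open)

    def __repr__(self) -> str:
        if self.is_empty:
            return "Interval(empty)"
        lb = "[" if self.lo_closed else "("
        rb = "]" if self.hi_closed else ")"
        return f"{lb}{self.lo:g}, {self.hi:g}{rb}"

    @staticmethod
    def nonnegative() -> "Interval":
        return Interval(0.0, _INF)


@dataclass(frozen=True)
class AffineIOMap:
    """Affine steady-state input/output map ``ybar = alpha*ubar + beta``.

    ``alpha`` is the steady-state gain, ``beta`` the basal offset; both are
    nonnegative for Metzler-Hurwitz unimolecular networks.
    """

    alpha: float
    beta: float

    def __call__(self, u: float) -> float:
        return self.alpha * u + self.beta

    def inverse(self, y: float) -> float:
        if self.alpha == 0:
            raise NoSupportingInputError("zero-gain map is not invertible")
        return (y - self.beta) / self.alpha


@dataclass
class GeneExpressionProcess:
    """Two-stage gene expression: mRNA ``x1`` and protein ``x2 = y``.

        x1dot = u + delta - gamma1*x1
        x2dot = k1*x1 - gamma2*x2

    ``u`` is an induced transcription rate (the actuated input) and
    ``delta`` a basal transcription rate acting as a constant or scheduled
    disturbance.
    """

    k1: float = 1.0
    gamma1: float = 1.0
    gamma2: float = 1.0
    delta: float | Schedule = 0.0

    def __post_init__(self) -> None:
        if min(self.k1, self.gamma1, self.gamma2) <= 0:
            raise ValidationError("k1, gamma1, gamma2 must be positive")
        self._delta = as_schedule(self.delta)

    n_species = 2
    species_names = ["x1", "x2"]
    output_index = 1
    input_index = 0

    def delta_at(self, t: float) -> float:
        return self._delta(t)

    def breakpoints(self) -> list[float]:
        return list(self._delta.breakpoints)

    def rhs(self, t: float, x: np.ndarray, u: float) -> np.ndarray:
        return np.array([
            u + self._delta(t) - self.gamma1 * x[0],
            self.k1 * x[0] - self.gamma2 * x[1],
        ])

    def output(self, x: np.ndarray) -> float:
        return float(x[self.output_index])

    def io_map(self, delta_bar: float | None = None) -> AffineIOMap:
        d = self._delta(_INF) if delta_bar is None else delta_bar
        g = self.k1 / (self.gamma1 * self.gamma2)
        return AffineIOMap(alpha=g, beta=g * d)

    def with_delta(self, delta) -> "GeneExpressionProcess":
        return GeneExpressionProcess(self.k1, self.gamma1, self.gamma2, delta)


@dataclass
class UnimolecularProcess:
    """Stable unimolecular network actuated by production of species 1.

    Propensities are affine, ``lambda(x) = W x + b``; the deterministic
    dynamics are ``xdot = S(Wx + b) + e1*u`` with output ``y = x_L``.
    ``S`` is species-by-reactions (L x K), ``W`` is K x L with nonnegative
    entries, ``b`` is a K-vector of nonnegative basal rates.
    """

    S: np.ndarray
    W: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        L, K = self.S.shape
        if self.W.shape != (K, L):
            raise ValidationError("W must be K x L for an L x K stoichiometry S")
        if self.b.shape != (K,):
            raise ValidationError("b must be a K-vector")
        if np.any(self.W < 0) or np.any(self.b < 0):
            raise ValidationError("W and b must be nonnegative")
        self.species_names = [f"x{i+1}" for i in range(L)]

    @property
    def n_species(self) -> int:
        return self.S.shape[0]

    input_index = 0

    @property
    def output_index(self) -> int:
        return self.n_species - 1

    def breakpoints(self) -> list[float]:
        return []

    @property
    def A(self) -> np.ndarray:
        return self.S @ self.W

    def rhs(self, t: float, x: np.ndarray, u: float) -> np.ndarray:
        dx = self.S @ (self.W @ x + self.b)
        dx[0] += u
        return dx

    def output(self, x: np.ndarray) -> float:
        return float(x[-1])

    def io_map(self, delta_bar: float | None = None) -> AffineIOMap:
        return io_map_unimolecular(self)


@dataclass(frozen=True)
class HurwitzMetzlerVerdict:
    hurwitz: bool
    metzler: bool
    max_real_part: float


def hurwitz_metzler_check(M: np.ndarray) -> HurwitzMetzlerVerdict:
    """Report whether a square matrix is Hurwitz (all eigenvalue real parts
    strictly negative) and Metzler (nonnegative off-diagonal entries)."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValidationError("matrix must be square")
    max_rp = float(np.max(np.linalg.eigvals(M).real))
    off = M - np.diag(np.diag(M))
    return HurwitzMetzlerVerdict(
        hurwitz=max_rp < 0, metzler=bool(np.all(off >= 0)), max_real_part=max_rp
    )


def io_map_unimolecular(proc: UnimolecularProcess) -> AffineIOMap:
    """Steady-state map of a stable unimolecular process.

    ``alpha = -eL' (SW)^-1 e1`` and ``beta = -eL' (SW)^-1 S b``; both are
    nonnegative because SW is Metzler and Hurwitz, hence has a nonpositive
    inverse.
    """
    A = proc.A
    verdict = hurwitz_metzler_check(A)
    if not verdict.hurwitz:
        raise StabilityError(
            f"SW is not Hurwitz (max eigenvalue real part {verdict.max_real_part:.3g}); "
            "steady-state map undefined"
        )
    Ainv = np.linalg.inv(A)
    eL = np.zeros(proc.n_species)
    eL[-1] = 1.0
    e1 = np.zeros(proc.n_species)
    e1[0] = 1.0
    alpha = float(-eL @ Ainv @ e1)
    beta = float(-eL @ Ainv @ proc.S @ proc.b)
    return AffineIOMap(alpha=alpha, beta=beta)


_ROOT_TOL = 1e-10
_BRACKET_CAP = 1e12


def supporting_input(io_map, r: float, U: Interval | None = None) -> float:
    """Input value whose steady-state output equals the setpoint ``r``.

    ``io_map`` is either an :class:`AffineIOMap` or a strictly increasing
    callable; the nonlinear case is solved by bracketed root-finding with a
    doubling upper bracket.  If ``U`` is given, feasibility is enforced.
    """
    if isinstance(io_map, AffineIOMap):
        u = io_map.inverse(r)
    else:
        lo = 0.0
        f_lo = io_map(lo) - r
        if abs(f_lo) <= _ROOT_TOL * max(1.0, abs(r)):
            u = lo
        elif f_lo > 0:
            raise NoSupportingInputError(
                f"setpoint {r:g} lies below the map's value at zero input"
            )
        else:
            hi = 1.0
            while io_map(hi) < r:
                hi *= 2.0
                if hi > _BRACKET_CAP:
                    raise NoSupportingInputError(
                        f"setpoint {r:g} not reached for any input up to {_BRACKET_CAP:g}"
                    )
            u = float(brentq(lambda v: io_map(v) - r, lo, hi,
                             rtol=_ROOT_TOL, xtol=1e-14))
    if U is not None and not U.contains(u):
        raise NoSupportingInputError(
            f"supporting input {u:g} is infeasible (outside {U})"
        )
    return u


def admissible_setpoints(io_map: AffineIOMap, U: Interval) -> Interval:
    """Set of setpoints supported by some feasible input: the image of the
    feasible-input set under the steady-state map."""
    if io_map.alpha == 0:
        return Interval(io_map.beta, io_map.beta)
    return U.image(io_map, increasing=io_map.alpha > 0)


def admissible_disturbances(
    family: Callable[[float], AffineIOMap],
    r: float,
    U: Interval,
    D: Interval,
    *,
    increasing_in_delta: bool = True,
) -> Interval:
    """Disturbance values in ``D`` that keep the setpoint ``r`` admissible.

    ``family`` maps a constant disturbance to the process's steady-state
    map, assumed monotone in the disturbance (offset nondecreasing when
    ``increasing_in_delta``).  The supporting input
    ``u(delta) = family(delta)^-1(r)`` is then monotone in delta, and the
    admissible set is the preimage of ``U`` — computed analytically for the
    affine family, with bisection-located finite boundary crossings.
    """

    def u_of(delta: float) -> float:
        return family(delta).inverse(r)

    lo_d = D.lo if math.isfinite(D.lo) else min(-1e12, r)
    hi_d = D.hi if math.isfinite(D.hi) else max(1e12, r)

    # u is monotone in delta: decreasing when the basal offset grows with it.
    u_lo, u_hi = u_of(lo_d), u_of(hi_d)
    feasible_lo, feasible_hi = U.contains(u_lo), U.contains(u_hi)
    if not feasible_lo and not feasible_hi and not (
        (u_lo > U.hi and u_hi < U.lo) or (u_hi > U.hi and u_lo < U.lo)
    ):
        return Interval.empty()

    def crossing(target: float) -> float:
        return float(brentq(lambda d: u_of(d) - target, lo_d, hi_d,
                            rtol=1e-12, xtol=1e-14))

    u_decreasing = u_hi < u_lo
    # Clamp the feasible-u window [U.lo, U.hi] back to delta space.
    lo_res, hi_res = lo_d, hi_d
    if u_decreasing:
        if u_lo > U.hi:
            lo_res = crossing(U.hi)
        if u_hi < U.lo:
            hi_res = crossing(U.lo)
    else:
        if u_lo < U.lo:
            lo_res = crossing(U.lo)
        if u_hi > U.hi:
            hi_res = crossing(U.hi)
    if lo_res > hi_res:
        return Interval.empty()
    result = Interval(lo_res, hi_res)
    return result.intersect(D)


def admissible_input_setpoints(out_set: Interval, hs: Callable[[float], float],
                               *, n_check: int = 33) -> Interval:
    """Map an admissible output-setpoint set through a strictly increasing
    sensing function: ``C_in = hs(C_out)``."""
    if out_set.is_empty:
        return Interval.empty()
    if not out_set.is_singleton:
        lo = out_set.lo if math.isfinite(out_set.lo) else out_set.hi - 1e6
        hi = out_set.hi if math.isfinite(out_set.hi) else out_set.lo + 1e6
        grid = np.linspace(lo, hi, n_check)
        vals = np.array([hs(g) for g in grid])
        if np.any(np.diff(vals) <= 0):
            raise ValidationError("sensing function must be strictly increasing "
                                  "on the output-setpoint set")
    return out_set.image(hs, increasing=True)
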