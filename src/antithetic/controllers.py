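"""Integral feedback controllers in closed loop with a process.

Covers the classical integral controller with actuator/sensor saturation,
the antithetic integral feedback (AIF) controller (two species Z1, Z2 that
sequester each other at rate eta), its saturated variant where actuation
and sensing pass through Hill-type monotone functions, and the
strong-sequestration reduced forms where the pair collapses to a signed
integrator state.  Fixed-point existence follows the saturation-aware
conditions: the setpoint must be admissible, and neither the sensor nor the
actuator may be saturated at steady state; when any condition fails the
closed loop has no (reachable, nonnegative) equilibrium and a controller
species winds up instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .crn import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    SteadyStateResult,
    Trajectory,
    ValidationError,
    find_steady_state,
    simulate_system,
)
from .processes import (
    AffineIOMap,
    Interval,
    NoSupportingInputError,
    supporting_input,
)
from .reduction import FastSequestrationSpec

__all__ = [
    "saturate",
    "hill",
    "identity",
    "SaturationFunctions",
    "ClassicalIFCParams",
    "AIFParams",
    "ClosedLoopSystem",
    "classical_ifc_loop",
    "aif_loop",
    "reduced_aif_loop",
    "aif_fast_seq_spec",
    "psi_actuation",
    "map_setpoints",
    "SensorSaturationError",
    "FixedPointReport",
    "fixed_point_exists",
]


def saturate(z: float, a: float, b: float) -> float:
    """Hard saturation: clamp ``z`` to ``[a, b]``."""
    if a >= b:
        raise ValidationError("saturation bounds must satisfy a < b")
    return min(max(z, a), b)


def hill(kappa: float) -> Callable[[float], float]:
    """Monotone Michaelis-Menten/Hill saturation ``s -> (s/kappa)/(1+s/kappa)``.

    Vanishes at zero, half-maximal at ``s = kappa``, saturates at one.
    """
    if kappa <= 0:
        raise ValidationError("Hill constant must be positive")

    def h(s: float) -> float:
        s = max(s, 0.0)
        return (s / kappa) / (1.0 + s / kappa)

    h.kappa = kappa  # type: ignore[attr-defined]
    return h


def identity(s: float) -> float:
    return s


@dataclass
class SaturationFunctions:
    """Actuation and sensing nonlinearities ``ha`` and ``hs``.

    Both must be monotonically increasing with ``ha(0) = hs(0) = 0``;
    the identity recovers the unsaturated controller.
    """

    ha: Callable[[float], float] = identity
    hs: Callable[[float], float] = identity

    @classmethod
    def hill_pair(cls, kappa_a: float, kappa_s: float) -> "SaturationFunctions":
        return cls(ha=hill(kappa_a), hs=hill(kappa_s))

    @classmethod
    def none(cls) -> "SaturationFunctions":
        return cls()


@dataclass
class ClassicalIFCParams:
    """Classical integral controller: ``vdot = KI*(r - w)`` with hard
    actuator range ``u_range`` and sensor range ``y_range``."""

    KI: float
    r: float
    u_range: tuple[float, float] = (-np.inf, np.inf)
    y_range: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self) -> None:
        if self.u_range[0] >= self.u_range[1] or self.y_range[0] >= self.y_range[1]:
            raise ValidationError("saturation ranges must have min < max")


@dataclass
class AIFParams:
    """AIF controller rates: setpoint production ``mu`` (Z1), sensing gain
    ``theta`` (Z2 produced at theta*hs(y)), sequestration rate ``eta`` and
    actuation gain ``k`` (input u = k*ha(z1)).

    The encoded input setpoint is ``r_in = mu/theta``; with identity sensing
    this is also the output setpoint.  An optional controller dilution rate
    (degradation of Z1 and Z2) defaults to zero.
    """

    mu: float
    theta: float
    eta: float
    k: float
    dilution: float = 0.0

    def __post_init__(self) -> None:
        if min(self.mu, self.theta, self.eta, self.k) <= 0:
            raise ValidationError("mu, theta, eta, k must be positive")
        if self.dilution < 0:
            raise ValidationError("dilution must be nonnegative")

    @property
    def r_in(self) -> float:
        return self.mu / self.theta

    @property
    def KI(self) -> float:
        return self.k * self.theta


@dataclass
class ClosedLoopSystem:
    """A process composed with a controller: a plain vector field on the
    stacked state ``(x_process, x_controller)``."""

    process: object
    state_names: list[str]
    _rhs: Callable[[float, np.ndarray], np.ndarray]
    controller_names: list[str]
    signed_species: frozenset = frozenset()
    info: dict = field(default_factory=dict)

    def rhs(self, t: float, s: np.ndarray) -> np.ndarray:
        return self._rhs(t, s)

    def breakpoints(self) -> list[float]:
        return list(self.process.breakpoints())

    @property
    def n_process(self) -> int:
        return self.process.n_species

    def output(self, s: np.ndarray) -> float:
        return self.process.output(np.asarray(s)[: self.n_process])

    def output_series(self, traj: Trajectory) -> np.ndarray:
        return np.array([self.output(row) for row in traj.states])

    def simulate(self, t_span, x0=None, *, t_eval=None, rtol=DEFAULT_RTOL,
                 atol=DEFAULT_ATOL, method="BDF") -> Trajectory:
        return simulate_system(self, x0, t_span, t_eval=t_eval,
                               rtol=rtol, atol=atol, method=method)

    def steady_state(self, x0=None, **kwargs) -> SteadyStateResult:
        return find_steady_state(self, x0, **kwargs)


def classical_ifc_loop(process, params: ClassicalIFCParams) -> ClosedLoopSystem:
    """Closed loop of a process with the classical saturated IFC.

    States are the process species followed by the integrator state ``v``;
    ``u = sat(v)``, ``w = sat(y)``, ``vdot = KI*(r - w)``.
    """
    n = process.n_species

    def rhs(t: float, s: np.ndarray) -> np.ndarray:
        x, v = s[:n], s[n]
        u = saturate(v, *params.u_range)
        y = process.output(x)
        w = saturate(y, *params.y_range)
        dx = process.rhs(t, x, u)
        return np.concatenate([dx, [params.KI * (params.r - w)]])

    return ClosedLoopSystem(
        process=process,
        state_names=[*process.species_names, "v"],
        _rhs=rhs,
        controller_names=["v"],
        signed_species=frozenset({"v"}),
        info={"controller": "classical-ifc", "params": params},
    )


def aif_loop(process, params: AIFParams,
             sats: SaturationFunctions | None = None,
             extra_z1_production: Callable | None = None,
             extra_z2_production: Callable | None = None) -> ClosedLoopSystem:
    """Closed loop of a process with the (possibly saturated) AIF controller.

        z1dot = mu      - eta*z1*z2
        z2dot = theta*hs(y) - eta*z1*z2
        u     = k*ha(z1)

    With identity saturations this is the basic AIF controller.  The
    optional extra production hooks (callables of the full state vector)
    support anti-windup circuitry layered on top.
    """
    sats = sats or SaturationFunctions.none()
    n = process.n_species

    def rhs(t: float, s: np.ndarray) -> np.ndarray:
        x = s[:n]
        z1, z2 = max(s[n], 0.0), max(s[n + 1], 0.0)
        y = process.output(x)
        u = params.k * sats.ha(z1)
        seq = params.eta * z1 * z2
        dz1 = params.mu - seq - params.dilution * z1
        dz2 = params.theta * sats.hs(y) - seq - params.dilution * z2
        if extra_z1_production is not None:
            dz1 += extra_z1_production(s)
        if extra_z2_production is not None:
            dz2 += extra_z2_production(s)
        dx = process.rhs(t, x, u)
        return np.concatenate([dx, [dz1, dz2]])

    return ClosedLoopSystem(
        process=process,
        state_names=[*process.species_names, "z1", "z2"],
        _rhs=rhs,
        controller_names=["z1", "z2"],
        info={"controller": "aif", "params": params, "sats": sats},
    )


def reduced_aif_loop(process, params: AIFParams,
                     sats: SaturationFunctions | None = None) -> ClosedLoopSystem:
    """Strong-sequestration reduced AIF loop on the signed coordinate
    ``z = z1 - z2``:

        zdot = mu - theta*hs(y),    u = k*ha(max(z, 0)).
    """
    sats = sats or SaturationFunctions.none()
    n = process.n_species

    def rhs(t: float, s: np.ndarray) -> np.ndarray:
        x, z = s[:n], s[n]
        y = process.output(x)
        u = params.k * sats.ha(max(z, 0.0))
        dx = process.rhs(t, x, u)
        return np.concatenate([dx, [params.mu - params.theta * sats.hs(y)]])

    return ClosedLoopSystem(
        process=process,
        state_names=[*process.species_names, "z"],
        _rhs=rhs,
        controller_names=["z"],
        signed_species=frozenset({"z"}),
        info={"controller": "aif-reduced", "params": params, "sats": sats},
    )


def aif_fast_seq_spec(process, params: AIFParams,
                      sats: SaturationFunctions | None = None,
                      x0: Sequence[float] | None = None,
                      a: float = 0.0, b: float = 0.0) -> FastSequestrationSpec:
    """Express the AIF closed loop as a fast-sequestration specification
    (W1 = mu, W2 = theta*hs(y)) so the reduction machinery applies to it."""
    sats = sats or SaturationFunctions.none()
    if x0 is None:
        x0 = np.zeros(process.n_species)

    def F(t, x, z1, z2):
        u = params.k * sats.ha(max(z1, 0.0))
        return process.rhs(t, x, u)

    def W1(t, x, z1, z2):
        return params.mu

    def W2(t, x, z1, z2):
        return params.theta * sats.hs(process.output(x))

    return FastSequestrationSpec(
        W1=W1, W2=W2, eta=params.eta, F=F, x0=np.asarray(x0, float),
        a=a, b=b, x_names=list(process.species_names),
    )


def psi_actuation(params: AIFParams, sats: SaturationFunctions) -> Callable[[float], float]:
    """Actuation nonlinearity of the reduced block diagram,
    ``psi_a(v) = k*ha(max(v, 0)/k)`` with ``v = k*z`` the integrator output.

    Equivalent to ``u = k*ha(max(z, 0))`` of the reduced controller.
    """

    def psi_a(v: float) -> float:
        return params.k * sats.ha(max(v, 0.0) / params.k)

    return psi_a


class SensorSaturationError(ValueError):
    """The encoded input setpoint exceeds the sensing function's range."""


_BRACKET_CAP = 1e12


def _monotone_inverse(g: Callable[[float], float], target: float,
                      err: type[Exception], what: str) -> float:
    """Invert a monotonically increasing g on [0, inf) by bracketing."""
    g0 = g(0.0)
    if target < g0 - 1e-12:
        raise err(f"{what}: target {target:g} below {g0:g} = value at zero")
    if abs(target - g0) <= 1e-14 * max(1.0, abs(target)):
        return 0.0
    hi = 1.0
    while g(hi) < target:
        hi *= 2.0
        if hi > _BRACKET_CAP:
            raise err(f"{what}: target {target:g} outside range (saturated)")
    return float(brentq(lambda s: g(s) - target, 0.0, hi, rtol=1e-12, xtol=1e-14))


def map_setpoints(hs: Callable[[float], float], r_in: float) -> float:
    """Output setpoint solving ``hs(r_out) = r_in`` for a strictly
    increasing sensing function; unique by monotonicity.

    Raises :class:`SensorSaturationError` when ``r_in`` exceeds the range of
    ``hs`` (the sensor would saturate at steady state)."""
    return _monotone_inverse(hs, r_in, SensorSaturationError, "sensing function")


@dataclass
class FixedPointReport:
    """Verdict on closed-loop fixed-point existence.

    ``failed_conditions`` is a subset of {"setpoint-inadmissible",
    "sensor-saturated", "actuator-saturated"}; the fixed point
    ``(ybar, ubar, vbar, wbar)`` is reported when it exists.  Exact
    boundary cases (e.g. the supporting input equals a saturation limit)
    count as existing but carry ``boundary_warning``.
    """

    exists: bool
    failed_conditions: list[str]
    fixed_point: dict | None = None
    boundary_warning: bool = False

    def __post_init__(self) -> None:
        assert self.exists == (len(self.failed_conditions) == 0)


def fixed_point_exists(
    io_map,
    *,
    r: float | None = None,
    r_in: float | None = None,
    u_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
    params: AIFParams | None = None,
    sats: SaturationFunctions | None = None,
    U: Interval | None = None,
) -> FixedPointReport:
    """Existence of the closed-loop fixed point under saturation.

    Two calling modes:

    * classical — pass the desired setpoint ``r`` together with hard
      ``u_range``/``y_range`` saturation bounds;
    * saturated AIF — pass the input setpoint ``r_in`` (or ``params`` whose
      ``mu/theta`` encodes it) plus ``sats`` and ``params``; actuation and
      sensing then run through ``psi_a``/``hs``.

    Checks, in order: the sensor is unsaturated at steady state, the
    setpoint is admissible (a feasible supporting input exists), and the
    actuator is unsaturated at steady state.  All must hold for the fixed
    point ``(ybar, ubar, vbar, wbar)`` to exist.
    """
    failed: list[str] = []
    boundary = False

    if sats is not None or r_in is not None:
        if params is None:
            raise ValidationError("saturated mode needs AIF params (for k)")
        sats = sats or SaturationFunctions.none()
        if r_in is None:
            r_in = params.r_in
        # 1. sensor condition: r_in in range(psi_s) = range(hs)
        try:
            r_out = map_setpoints(sats.hs, r_in)
        except SensorSaturationError:
            failed.append("sensor-saturated")
            return FixedPointReport(False, failed)
        # 2. admissibility of the output setpoint
        U = U if U is not None else Interval.nonnegative()
        try:
            u_bar = supporting_input(io_map, r_out, U=U)
        except NoSupportingInputError:
            failed.append("setpoint-inadmissible")
            return FixedPointReport(False, failed)
        # 3. actuator condition: u_bar in range(psi_a)
        psi_a = psi_actuation(params, sats)
        try:
            v_bar = _monotone_inverse(psi_a, u_bar, SensorSaturationError,
                                      "actuation function")
        except SensorSaturationError:
            failed.append("actuator-saturated")
            return FixedPointReport(False, failed)
        fp = {"y": r_out, "u": u_bar, "v": v_bar, "w": r_in}
        return FixedPointReport(True, [], fp, boundary_warning=boundary)

    # classical mode
    if r is None:
        raise ValidationError("classical mode needs the setpoint r")
    u_range = u_range or (-np.inf, np.inf)
    y_range = y_range or (-np.inf, np.inf)
    U = U if U is not None else Interval(-np.inf, np.inf)
    try:
        u_bar = supporting_input(io_map, r, U=U)
    except NoSupportingInputError:
        failed.append("setpoint-inadmissible")
    else:
        if not (y_range[0] <= r <= y_range[1]):
            failed.append("sensor-saturated")
        elif r in (y_range[0], y_range[1]):
            boundary = True
        if not (u_range[0] <= u_bar <= u_range[1]):
            failed.append("actuator-saturated")
        elif u_bar in (u_range[0], u_range[1]):
            boundary = True
    if failed:
        return FixedPointReport(False, failed)
    fp = {"y": r, "u": u_bar, "v": u_bar, "w": r}
    return FixedPointReport(True, [], fp, boundary_warning=boundary)
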