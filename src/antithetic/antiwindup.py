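"""Anti-windup circuitry for the AIF controller.

Three topologies share one idea: the controller runs as a pure integral
controller while Z1 and Z2 stay below preset thresholds, and switch
circuits intervene only beyond them.

* Topology I — high Z2 triggers extra production of Z1 (and vice versa),
  sequestering the overabundant species.
* Topology II — high Z1 triggers its own catalytic degradation (and
  symmetrically for Z2).
* Topology III — high Z1 represses its own production (and symmetrically).

Each topology exists in two forms: a phenomenological one where the switch
is an explicit threshold function of the controller species, and a full
reaction-network one where each switch is a sequestration pair (V1, V2) /
(W1, W2) whose strong-sequestration steady state realizes the threshold.
In the strong-sequestration limit, topologies I and II reduce to
*conditional integration*: the integrator output ``v = k*(z1 - z2)``
integrates the error inside a safe band and leaks back toward the band
outside it, trading a bounded steady-state error for bounded controller
states.  Topology III reduces to *reference/sensor conditioning*, scaling
down the setpoint or the sensed signal as ``v`` leaves the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .crn import Trajectory, ValidationError
from .controllers import (
    AIFParams,
    ClosedLoopSystem,
    SaturationFunctions,
    identity,
    psi_actuation,
)

__all__ = [
    "SwitchShape",
    "linear_above_threshold",
    "hill_repression",
    "TopologyParams",
    "topology_loop",
    "topology_I_loop",
    "topology_II_loop",
    "topology_III_loop",
    "phenomenological_loop",
    "ReducedAWParams",
    "reduced_conditional_integration_loop",
    "steady_state_error",
    "conditioning_factors",
    "WindupReport",
    "windup_metrics",
]


@dataclass(frozen=True)
class SwitchShape:
    """Phenomenological switch function.

    ``linear-above-threshold``: h(s) = alpha*max(s - beta, 0) — zero below
    the threshold beta, then linear with slope alpha (continuous at beta).
    ``hill-repression``: h(s) = alpha/(1 + s/kappa) — decreasing from
    h(0) = alpha with half-repression at kappa.
    """

    kind: str
    alpha: float
    beta_or_kappa: float

    def __post_init__(self) -> None:
        if self.kind not in ("linear-above-threshold", "hill-repression"):
            raise ValidationError(f"unknown switch shape {self.kind!r}")
        if self.alpha < 0 or self.beta_or_kappa < 0:
            raise ValidationError("switch shape parameters must be nonnegative")
        if self.kind == "hill-repression" and self.beta_or_kappa == 0:
            raise ValidationError("hill repression needs kappa > 0")

    def __call__(self, s: float) -> float:
        s = max(s, 0.0)
        if self.kind == "linear-above-threshold":
            return self.alpha * max(s - self.beta_or_kappa, 0.0)
        return self.alpha / (1.0 + s / self.beta_or_kappa)


def linear_above_threshold(alpha: float, beta: float) -> SwitchShape:
    return SwitchShape("linear-above-threshold", alpha, beta)


def hill_repression(alpha: float, kappa: float) -> SwitchShape:
    return SwitchShape("hill-repression", alpha, kappa)


@dataclass
class TopologyParams:
    """Full-CRN anti-windup parameters.

    The red switch (V1, V2) and blue switch (W1, W2) are sequestration
    pairs with thresholds ``v0`` and ``w0`` (production rates of V1/W1).
    Topology I drives the red switch with z2 and the blue with z1;
    topologies II and III drive each switch with its own Z species.
    ``g1, g2`` shape the switch inputs and ``h1, h2`` the readouts; the
    defaults are identity for topologies I/II and Hill repression (pinned
    to the nominal production rates at zero) for topology III.
    """

    topology: str
    aif: AIFParams
    sats: SaturationFunctions = field(default_factory=SaturationFunctions.none)
    v0: float = 10.0
    w0: float = 10.0
    eta_v: float = 100.0
    eta_w: float = 100.0
    delta_v1: float = 1.0
    delta_v2: float = 1.0
    delta_w1: float = 1.0
    delta_w2: float = 1.0
    g1: Callable[[float], float] = identity
    g2: Callable[[float], float] = identity
    h1: Callable[[float], float] | None = None
    h2: Callable[[float], float] | None = None
    kappa1: float = 1.0
    kappa2: float = 1.0

    def __post_init__(self) -> None:
        if self.topology not in ("I", "II", "III"):
            raise ValidationError("topology must be 'I', 'II' or 'III'")
        if min(self.v0, self.w0, self.eta_v, self.eta_w) <= 0:
            raise ValidationError("switch thresholds and rates must be positive")
        if self.h1 is None:
            self.h1 = (hill_repression(self.aif.mu, self.kappa1)
                       if self.topology == "III" else identity)
        if self.h2 is None:
            # For topology III the blue readout is a relative repression
            # factor multiplying the nominal sensing rate.
            self.h2 = (hill_repression(1.0, self.kappa2)
                       if self.topology == "III" else identity)


def topology_loop(p: TopologyParams, process) -> ClosedLoopSystem:
    """Closed loop with the full-CRN anti-windup circuitry.

    States are the process species, (z1, z2), the red switch (v1, v2) and
    the blue switch (w1, w2); actuation is ``u = k*ha(z1)`` as in the base
    controller.
    """
    n = process.n_species
    aif, sats = p.aif, p.sats

    def rhs(t: float, s: np.ndarray) -> np.ndarray:
        x = s[:n]
        z1, z2 = max(s[n], 0.0), max(s[n + 1], 0.0)
        v1, v2 = max(s[n + 2], 0.0), max(s[n + 3], 0.0)
        w1, w2 = max(s[n + 4], 0.0), max(s[n + 5], 0.0)
        y = process.output(x)
        u = aif.k * sats.ha(z1)
        seq = aif.eta * z1 * z2

        if p.topology == "I":
            dz1 = aif.mu + p.h1(v2) - seq
            dz2 = aif.theta * sats.hs(y) + p.h2(w2) - seq
            red_in, blue_in = p.g1(z2), p.g2(z1)
        elif p.topology == "II":
            dz1 = aif.mu - seq - p.h1(v2) * z1
            dz2 = aif.theta * sats.hs(y) - seq - p.h2(w2) * z2
            red_in, blue_in = p.g1(z1), p.g2(z2)
        else:  # III
            dz1 = p.h1(v2) - seq
            dz2 = aif.theta * sats.hs(y) * p.h2(w2) / p.h2(0.0) - seq
            red_in, blue_in = p.g1(z1), p.g2(z2)

        dz1 -= aif.dilution * z1
        dz2 -= aif.dilution * z2
        dv1 = p.v0 - p.eta_v * v1 * v2 - p.delta_v1 * v1
        dv2 = red_in - p.eta_v * v1 * v2 - p.delta_v2 * v2
        dw1 = p.w0 - p.eta_w * w1 * w2 - p.delta_w1 * w1
        dw2 = blue_in - p.eta_w * w1 * w2 - p.delta_w2 * w2
        dx = process.rhs(t, x, u)
        return np.concatenate([dx, [dz1, dz2, dv1, dv2, dw1, dw2]])

    return ClosedLoopSystem(
        process=process,
        state_names=[*process.species_names, "z1", "z2", "v1", "v2", "w1", "w2"],
        _rhs=rhs,
        controller_names=["z1", "z2", "v1", "v2", "w1", "w2"],
        info={"controller": f"aif-antiwindup-{p.topology}", "params": p},
    )


def topology_I_loop(p: TopologyParams, process) -> ClosedLoopSystem:
    if p.topology != "I":
        raise ValidationError("params are not for topology I")
    return topology_loop(p, process)


def topology_II_loop(p: TopologyParams, process) -> ClosedLoopSystem:
    if p.topology != "II":
        raise ValidationError("params are not for topology II")
    return topology_loop(p, process)


def topology_III_loop(p: TopologyParams, process) -> ClosedLoopSystem:
    if p.topology != "III":
        raise ValidationError("params are not for topology III")
    return topology_loop(p, process)


def phenomenological_loop(topology: str, process, aif: AIFParams,
                          shape1: SwitchShape, shape2: SwitchShape,
                          sats: SaturationFunctions | None = None) -> ClosedLoopSystem:
    """Anti-windup loop with explicit threshold functions of (z1, z2) in
    place of the switch networks (the idealized strong-sequestration form).

    Topology I adds production ``shape1(z2)`` to Z1 and ``shape2(z1)`` to
    Z2; topology II removes Z1 at the absolute rate ``shape1(z1)`` and Z2
    at ``shape2(z2)``; topology III multiplies the production rates by the
    decreasing shapes, normalized to one at zero.
    """
    sats = sats or SaturationFunctions.none()
    n = process.n_species

    def rhs(t: float, s: np.ndarray) -> np.ndarray:
        x = s[:n]
        z1, z2 = max(s[n], 0.0), max(s[n + 1], 0.0)
        y = process.output(x)
        u = aif.k * sats.ha(z1)
        seq = aif.eta * z1 * z2
        sense = aif.theta * sats.hs(y)
        if topology == "I":
            dz1 = aif.mu + shape1(z2) - seq
            dz2 = sense + shape2(z1) - seq
        elif topology == "II":
            dz1 = aif.mu - seq - shape1(z1)
            dz2 = sense - seq - shape2(z2)
        elif topology == "III":
            dz1 = shape1(z1) - seq
            dz2 = sense * shape2(z2) / shape2(0.0) - seq
        else:
            raise ValidationError("topology must be 'I', 'II' or 'III'")
        dx = process.rhs(t, x, u)
        return np.concatenate([dx, [dz1, dz2]])

    return ClosedLoopSystem(
        process=process,
        state_names=[*process.species_names, "z1", "z2"],
        _rhs=rhs,
        controller_names=["z1", "z2"],
        info={"controller": f"aif-antiwindup-{topology}-phenomenological"},
    )


@dataclass
class ReducedAWParams:
    """Parameters of the reduced conditional-integration controller.

    ``(alpha1, beta1)`` belong to the red switch and ``(alpha2, beta2)`` to
    the blue one; the safe integration band of ``v = k*(z1 - z2)`` is
    ``[-k*beta_i, k*beta_j]`` with ``(i, j) = (1, 2)`` for topology I and
    ``(2, 1)`` for topology II.
    """

    KI: float
    k: float
    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    theta: float
    r_in: float
    topology: str = "I"

    def __post_init__(self) -> None:
        if min(self.KI, self.k, self.alpha1, self.alpha2, self.theta) <= 0:
            raise ValidationError("gains must be positive")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValidationError("thresholds must be nonnegative")
        if self.topology not in ("I", "II"):
            raise ValidationError("conditional integration covers topologies I and II")

    @property
    def band(self) -> tuple[float, float]:
        """Safe band [-k*beta_i, k*beta_j] of the integrator output v."""
        a_i, b_i, a_j, b_j = self._ij()
        return (-self.k * b_i, self.k * b_j)

    def _ij(self) -> tuple[float, float, float, float]:
        if self.topology == "I":
            return self.alpha1, self.beta1, self.alpha2, self.beta2
        return self.alpha2, self.beta2, self.alpha1, self.beta1

    def vdot(self, e: float, v: float) -> float:
        """Piecewise integrator law: pure integration inside the band, a
        leak back toward the nearest band edge outside it."""
        a_i, b_i, a_j, b_j = self._ij()
        lo, hi = -self.k * b_i, self.k * b_j
        if v < lo:
            return self.KI * e - a_i * (v + self.k * b_i)
        if v > hi:
            return self.KI * e - a_j * (v - self.k * b_j)
        return self.KI * e


def reduced_conditional_integration_loop(
    p: ReducedAWParams, process,
    sats: SaturationFunctions | None = None,
) -> ClosedLoopSystem:
    """Closed loop of the reduced conditional-integration controller with a
    process; error ``e = r_in - hs(y)``, actuation through
    ``psi_a(v) = k*ha(max(v, 0)/k)``."""
    sats = sats or SaturationFunctions.none()
    n = process.n_species
    aif_like = AIFParams(mu=p.r_in * p.theta, theta=p.theta,
                         eta=1.0, k=p.k)  # eta unused in the reduced form
    psi_a = psi_actuation(aif_like, sats)

    def rhs(t: float, s: np.ndarray) -> np.ndarray:
        x, v = s[:n], s[n]
        y = process.output(x)
        e = p.r_in - sats.hs(y)
        u = psi_a(v)
        dx = process.rhs(t, x, u)
        return np.concatenate([dx, [p.vdot(e, v)]])

    return ClosedLoopSystem(
        process=process,
        state_names=[*process.species_names, "v"],
        _rhs=rhs,
        controller_names=["v"],
        signed_species=frozenset({"v"}),
        info={"controller": "conditional-integration", "params": p},
    )


def steady_state_error(v_bar: float, p: ReducedAWParams) -> float:
    """Steady-state error of the conditional-integration loop as a function
    of the settled integrator output: zero inside the safe band and
    proportional to the excursion outside it (continuous at the edges)."""
    a_i, b_i, a_j, b_j = p._ij()
    lo, hi = -p.k * b_i, p.k * b_j
    if v_bar < lo:
        return (a_i / p.KI) * (v_bar + p.k * b_i)
    if v_bar > hi:
        return (a_j / p.KI) * (v_bar - p.k * b_j)
    return 0.0


def conditioning_factors(v: float, p: ReducedAWParams) -> tuple[float, float]:
    """Reference and sensor conditioning factors of topology III.

    High positive ``v`` scales the input setpoint down by
    ``k*alpha1/(k*alpha1 + v - k*beta1)``; low negative ``v`` scales the
    sensed signal by ``k*alpha2/(k*alpha2 - v - k*beta2)``.  Both factors
    lie in (0, 1] and equal one inside the band ``[-k*beta2, k*beta1]``.
    """
    rho_ref = 1.0
    rho_sense = 1.0
    if v > p.k * p.beta1:
        rho_ref = (p.k * p.alpha1) / (p.k * p.alpha1 + v - p.k * p.beta1)
    if v < -p.k * p.beta2:
        rho_sense = (p.k * p.alpha2) / (p.k * p.alpha2 - v - p.k * p.beta2)
    return rho_ref, rho_sense


@dataclass
class WindupReport:
    peaks: dict[str, float]
    time_above_threshold: dict[str, float]
    recovery_time: float  # time after the disturbance window ends; inf if never


def windup_metrics(
    traj: Trajectory,
    *,
    controller_species: Sequence[str],
    threshold: float,
    error: np.ndarray,
    setpoint: float,
    disturbance_window: tuple[float, float] | None,
    tolerance_fraction: float = 0.05,
) -> WindupReport:
    """Peak controller-species levels, time spent above a threshold, and
    post-disturbance recovery time (first time the error magnitude drops
    below 5 % of the setpoint after the disturbance ends)."""
    if disturbance_window is None:
        raise ValidationError("the disturbance window must be marked")
    error = np.asarray(error, dtype=float)
    if error.shape != traj.times.shape:
        raise ValidationError("error signal must align with trajectory times")
    t = traj.times
    peaks, above = {}, {}
    for name in controller_species:
        series = traj.species(name)
        peaks[name] = float(series.max())
        mask = series > threshold
        above[name] = float(np.trapezoid(mask.astype(float), t))
    t_end = disturbance_window[1]
    tol = tolerance_fraction * abs(setpoint)
    after = t >= t_end
    # Sustained recovery: first time after the disturbance beyond which the
    # error stays inside the 5 % band (a transient crossing does not count).
    bad = after & (np.abs(error) >= tol)
    if not np.any(after & ~bad):
        recovery = float("inf")
    elif not np.any(bad):
        recovery = 0.0
    else:
        last_bad = t[bad][-1]
        later = t[after & (t > last_bad)]
        recovery = float(later[0] - t_end) if later.size else float("inf")
    return WindupReport(peaks, above, recovery)
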