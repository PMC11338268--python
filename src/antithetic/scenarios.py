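"""Built-in closed-loop scenarios.

Each scenario packages a process, a controller, a disturbance or setpoint
schedule, and machine-checkable expected outcomes.  The parameter sets are
the package's canonical study conditions:

* ``aif-windup`` — unit-rate gene expression under the basic AIF
  controller (mu=10, eta=100, k=theta=1) with the basal-transcription
  disturbance stepped across its admissible range [0, 10]: robust perfect
  adaptation inside the range, windup of Z2 beyond it.
* ``saturated-setpoint`` — gene expression with Hill actuation and sensing
  (theta=15, k=8, kappa_a=kappa_s=5, delta=5); the setpoint production mu
  is stepped across the admissible band theta*hs([5, 13]) ~ [7.5, 10.83],
  so the middle plateau winds Z1 up.
* ``saturated-disturbance`` — same loop with mu=10 fixed and the
  disturbance stepped across its admissible interval [2, 10].
* ``antiwindup`` / ``antiwindup-off`` — the saturated loop augmented (or
  not) with the topology-I switch circuits (eta_v=eta_w=100, v0=10, w0=20,
  identity switch maps, unit switch degradation) under an inadmissible
  disturbance pulse.

Schedule plateaus are generous (>= 50 time units) so every steady state is
observable; all values are config-overridable through the builders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .crn import Schedule, Trajectory
from .controllers import (
    AIFParams,
    ClosedLoopSystem,
    SaturationFunctions,
    aif_loop,
)
from .processes import GeneExpressionProcess
from .antiwindup import TopologyParams, topology_loop

__all__ = [
    "Outcome",
    "Scenario",
    "aif_windup_scenario",
    "saturated_setpoint_scenario",
    "saturated_disturbance_scenario",
    "antiwindup_scenario",
    "SCENARIOS",
    "get_scenario",
]

# Saturated-loop constants shared by the setpoint/disturbance/anti-windup
# scenarios: process k1=gamma1=gamma2=1; controller theta=15, eta=100, k=8
# with Hill constants kappa_a=kappa_s=5.  The encoded input setpoint
# mu/theta = 2/3 maps through hs^-1 to an output setpoint of 10.
SAT_THETA = 15.0
SAT_ETA = 100.0
SAT_K = 8.0
SAT_KAPPA = 5.0
SAT_MU = 10.0
SAT_DELTA = 5.0
AW_V0 = 10.0
AW_W0 = 20.0
AW_ETA = 100.0


@dataclass
class Outcome:
    name: str
    passed: bool
    measured: float
    detail: str = ""


@dataclass
class Scenario:
    name: str
    description: str
    system: ClosedLoopSystem
    horizon: float
    checks: Callable[[Trajectory, ClosedLoopSystem], list[Outcome]]
    meta: dict = field(default_factory=dict)

    def run(self, *, n_points: int = 2001) -> Trajectory:
        t_eval = np.linspace(0.0, self.horizon, n_points)
        return self.system.simulate((0.0, self.horizon), t_eval=t_eval)

    def check(self, traj: Trajectory | None = None) -> list[Outcome]:
        if traj is None:
            traj = self.run()
        return self.checks(traj, self.system)


def _value_at(traj: Trajectory, name: str, t: float) -> float:
    return float(np.interp(t, traj.times, traj.species(name)))


def aif_windup_scenario(
    *,
    mu: float = 10.0,
    eta: float = 100.0,
    delta_schedule: Schedule | None = None,
    horizon: float = 250.0,
) -> Scenario:
    """Basic AIF + gene expression with the disturbance stepped
    0 -> 5 -> 12 -> 5, crossing the admissible boundary at 10."""
    sched = delta_schedule or Schedule((0.0, 50.0, 100.0, 150.0), (0.0, 5.0, 12.0, 5.0))
    process = GeneExpressionProcess(delta=sched)
    params = AIFParams(mu=mu, theta=1.0, eta=eta, k=1.0)
    system = aif_loop(process, params)
    r = params.r_in

    def checks(traj: Trajectory, sys_: ClosedLoopSystem) -> list[Outcome]:
        y_adm = _value_at(traj, "x2", 99.0)
        z2_start = _value_at(traj, "z2", 105.0)
        z2_end = _value_at(traj, "z2", 149.0)
        y_final = _value_at(traj, "x2", horizon)
        return [
            Outcome("output-tracks-setpoint-under-admissible-disturbance",
                    abs(y_adm - r) < 1e-2, y_adm),
            Outcome("z2-accumulates-under-inadmissible-disturbance",
                    z2_end > z2_start + 1.0, z2_end - z2_start),
            Outcome("output-recovers-after-disturbance-returns",
                    abs(y_final - r) < 1e-2, y_final),
        ]

    return Scenario(
        name="aif-windup",
        description="AIF-controlled gene expression; disturbance steps across "
                    "the admissible range [0, 10]",
        system=system, horizon=horizon, checks=checks,
        meta={"setpoint": r, "admissible_disturbances": (0.0, 10.0)},
    )


def _saturated_process(delta) -> GeneExpressionProcess:
    return GeneExpressionProcess(k1=1.0, gamma1=1.0, gamma2=1.0, delta=delta)


def _saturated_controller(mu: float) -> tuple[AIFParams, SaturationFunctions]:
    params = AIFParams(mu=mu, theta=SAT_THETA, eta=SAT_ETA, k=SAT_K)
    sats = SaturationFunctions.hill_pair(SAT_KAPPA, SAT_KAPPA)
    return params, sats


class _ScheduledMu:
    """AIF loop variant whose setpoint-encoding rate mu follows a schedule."""

    def __init__(self, process, params: AIFParams, sats: SaturationFunctions,
                 mu_schedule: Schedule) -> None:
        self.base = aif_loop(process, params, sats)
        self.params = params
        self.sats = sats
        self.mu_schedule = mu_schedule
        self.state_names = self.base.state_names
        self.process = process

    def rhs(self, t: float, s: np.ndarray) -> np.ndarray:
        ds = self.base.rhs(t, s)
        n = self.process.n_species
        ds[n] += self.mu_schedule(t) - self.params.mu  # swap in scheduled mu
        return ds

    def breakpoints(self) -> list[float]:
        return sorted(set(self.base.breakpoints()) | set(self.mu_schedule.breakpoints))

    def output(self, s) -> float:
        return self.base.output(s)

    def output_series(self, traj) -> np.ndarray:
        return self.base.output_series(traj)

    def simulate(self, t_span, x0=None, **kw):
        from .crn import simulate_system
        return simulate_system(self, x0, t_span, **kw)

    @property
    def controller_names(self):
        return self.base.controller_names

    @property
    def info(self):
        return self.base.info


def saturated_setpoint_scenario(
    *,
    mu_schedule: Schedule | None = None,
    horizon: float = 400.0,
) -> Scenario:
    """Saturated AIF loop with a fixed disturbance and the setpoint rate mu
    stepped outside its admissible band (windup of Z1)."""
    sched = mu_schedule or Schedule((0.0, 100.0, 160.0), (10.0, 12.0, 10.0))
    process = _saturated_process(SAT_DELTA)
    params, sats = _saturated_controller(sched.values[0])
    system = _ScheduledMu(process, params, sats, sched)

    def checks(traj: Trajectory, sys_) -> list[Outcome]:
        y_adm = _value_at(traj, "x2", 99.0)
        z1_start = _value_at(traj, "z1", 105.0)
        z1_end = _value_at(traj, "z1", 159.0)
        y_final = _value_at(traj, "x2", horizon)
        return [
            Outcome("output-tracks-admissible-setpoint", abs(y_adm - 10.0) < 1e-2, y_adm),
            Outcome("z1-accumulates-under-inadmissible-setpoint",
                    z1_end > z1_start + 1.0, z1_end - z1_start),
            Outcome("output-recovers-after-setpoint-returns",
                    abs(y_final - 10.0) < 1e-2, y_final),
        ]

    return Scenario(
        name="saturated-setpoint",
        description="Saturated AIF loop; setpoint production stepped across "
                    "the admissible band",
        system=system, horizon=horizon, checks=checks,
        meta={"r_out": 10.0, "admissible_mu": (7.5, SAT_THETA * (13.0 / 18.0))},
    )


def saturated_disturbance_scenario(
    *,
    delta_schedule: Schedule | None = None,
    horizon: float = 320.0,
) -> Scenario:
    """Saturated AIF loop with mu=10 fixed and the disturbance stepped
    across its admissible interval [2, 10] (windup of Z2 above it)."""
    sched = delta_schedule or Schedule((0.0, 100.0, 160.0), (5.0, 12.0, 5.0))
    process = _saturated_process(sched)
    params, sats = _saturated_controller(SAT_MU)
    system = aif_loop(process, params, sats)

    def checks(traj: Trajectory, sys_) -> list[Outcome]:
        y_adm = _value_at(traj, "x2", 99.0)
        z2_start = _value_at(traj, "z2", 105.0)
        z2_end = _value_at(traj, "z2", 159.0)
        y_final = _value_at(traj, "x2", horizon)
        return [
            Outcome("output-tracks-setpoint-under-admissible-disturbance",
                    abs(y_adm - 10.0) < 1e-2, y_adm),
            Outcome("z2-accumulates-under-inadmissible-disturbance",
                    z2_end > z2_start + 1.0, z2_end - z2_start),
            Outcome("output-recovers-after-disturbance-returns",
                    abs(y_final - 10.0) < 1e-2, y_final),
        ]

    return Scenario(
        name="saturated-disturbance",
        description="Saturated AIF loop; disturbance stepped across its "
                    "admissible interval [2, 10]",
        system=system, horizon=horizon, checks=checks,
        meta={"r_out": 10.0, "admissible_disturbances": (2.0, 10.0)},
    )


def antiwindup_scenario(
    enabled: bool = True,
    *,
    delta_schedule: Schedule | None = None,
    horizon: float = 250.0,
) -> Scenario:
    """Saturated AIF loop, optionally protected by the topology-I switch
    circuits, under an inadmissible disturbance pulse (5 -> 15 -> 5, the
    pulse overshooting the admissible upper boundary by 50 %)."""
    sched = delta_schedule or Schedule((0.0, 50.0, 100.0), (5.0, 15.0, 5.0))
    process = _saturated_process(sched)
    params, sats = _saturated_controller(SAT_MU)
    if enabled:
        top = TopologyParams(topology="I", aif=params, sats=sats,
                             v0=AW_V0, w0=AW_W0, eta_v=AW_ETA, eta_w=AW_ETA)
        system = topology_loop(top, process)
    else:
        system = aif_loop(process, params, sats)

    def checks(traj: Trajectory, sys_) -> list[Outcome]:
        y_final = _value_at(traj, "x2", horizon)
        z2_peak = float(traj.species("z2").max())
        out = [
            Outcome("output-settles-after-pulse", abs(y_final - 10.0) < 5e-2, y_final),
        ]
        if enabled:
            # Switch dormancy before the pulse (admissible phase).
            pre = traj.times < 50.0
            v2_pre = float(traj.species("v2")[pre].max())
            out.append(Outcome("red-switch-dormant-in-admissible-phase",
                               v2_pre < 0.01 * params.mu, v2_pre))
            out.append(Outcome("z2-bounded-by-antiwindup", z2_peak < 2 * AW_V0, z2_peak))
        return out

    return Scenario(
        name="antiwindup" if enabled else "antiwindup-off",
        description="Saturated AIF loop with topology-I anti-windup "
                    f"{'enabled' if enabled else 'disabled'} under an "
                    "inadmissible disturbance pulse",
        system=system, horizon=horizon, checks=checks,
        meta={"pulse": (50.0, 100.0), "r_out": 10.0, "enabled": enabled},
    )


SCENARIOS: dict[str, Callable[[], Scenario]] = {
    "aif-windup": aif_windup_scenario,
    "saturated-setpoint": saturated_setpoint_scenario,
    "saturated-disturbance": saturated_disturbance_scenario,
    "antiwindup": antiwindup_scenario,
    "antiwindup-off": lambda: antiwindup_scenario(False),
}


def get_scenario(name: str) -> Scenario:
    try:
        return SCENARIOS[name]()
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(SCENARIOS))}"
        ) from None
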