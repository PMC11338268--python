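"""Sequestration-based biomolecular switches.

Two species V1 and V2 sequester each other at rate ``eta_v`` while
degrading separately:

    v1dot = u0 - eta_v*v1*v2 - delta1*v1
    v2dot = u  - eta_v*v1*v2 - delta2*v2

``u`` (production of V2) is the switch input and ``u0`` (production of V1)
sets the threshold.  In the strong-sequestration limit the steady-state
response is the rectified linear form

    v2bar = max(u - u0, 0) / delta2

so V2 stays at zero below threshold and rises with slope ``1/delta2``
above it.  The readout is a monotone function of v2 — increasing for an
activator switch, decreasing for a repressor switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .crn import Reaction, ReactionNetwork, ValidationError, find_steady_state
from .reduction import FastSequestrationSpec

__all__ = [
    "SequestrationSwitch",
    "switch_rhs",
    "switch_network",
    "reduced_switch_network",
    "switch_fast_seq_spec",
    "switch_steady_state_closed_form",
    "sweep_response",
]


@dataclass
class SequestrationSwitch:
    """Parameters of a sequestration switch.

    ``output_fn`` maps the V2 concentration to the switch output; it must be
    increasing in activator mode and decreasing in repressor mode.
    """

    u0: float
    eta_v: float
    delta1: float = 1.0
    delta2: float = 1.0
    mode: str = "activator"
    output_fn: Callable[[float], float] = field(default=lambda v2: v2)

    def __post_init__(self) -> None:
        if min(self.u0, self.eta_v, self.delta1, self.delta2) <= 0:
            raise ValidationError("switch rates must be positive")
        if self.mode not in ("activator", "repressor"):
            raise ValidationError("mode must be 'activator' or 'repressor'")
        probe = np.linspace(0.0, max(3 * self.u0 / self.delta2, 1.0), 17)
        vals = np.array([self.output_fn(p) for p in probe])
        d = np.diff(vals)
        if self.mode == "activator" and np.any(d < -1e-12):
            raise ValidationError("activator readout must be nondecreasing")
        if self.mode == "repressor" and np.any(d > 1e-12):
            raise ValidationError("repressor readout must be nonincreasing")

    def output(self, v2: float) -> float:
        return self.output_fn(v2)


def switch_rhs(sw: SequestrationSwitch, u: float) -> Callable[[float, np.ndarray], np.ndarray]:
    """Vector field on (v1, v2) for a constant input u."""
    if u < 0:
        raise ValidationError("switch input must be nonnegative")

    def rhs(t: float, v: np.ndarray) -> np.ndarray:
        v1, v2 = max(v[0], 0.0), max(v[1], 0.0)
        seq = sw.eta_v * v1 * v2
        return np.array([
            sw.u0 - seq - sw.delta1 * v1,
            u - seq - sw.delta2 * v2,
        ])

    return rhs


def switch_network(sw: SequestrationSwitch, u: float) -> ReactionNetwork:
    """The switch as a five-reaction network (for ODE or SSA simulation)."""
    return ReactionNetwork(
        species_names=["v1", "v2"],
        reactions=[
            Reaction((1, 0), lambda x, t: sw.u0, "production-v1"),
            Reaction((0, 1), lambda x, t: u, "production-v2"),
            Reaction((-1, 0), lambda x, t: sw.delta1 * x[0], "degradation-v1"),
            Reaction((0, -1), lambda x, t: sw.delta2 * x[1], "degradation-v2"),
            Reaction((-1, -1), lambda x, t: sw.eta_v * x[0] * x[1], "sequestration"),
        ],
        parameters={"u0": sw.u0, "u": u, "eta_v": sw.eta_v,
                    "delta1": sw.delta1, "delta2": sw.delta2},
    )


def reduced_switch_network(sw: SequestrationSwitch, u: float) -> ReactionNetwork:
    """Strong-sequestration limit of the switch as a jump process on the
    signed coordinate ``z = v1 - v2``.

    Production of V1 or degradation of V2 raises z; production of V2 or
    degradation of V1 lowers it; sequestration cancels and disappears:

        z -> z+1 at rate u0 + delta2*max(-z, 0)
        z -> z-1 at rate u  + delta1*max(z, 0)
    """
    return ReactionNetwork(
        species_names=["z"],
        reactions=[
            Reaction((1,), lambda x, t: sw.u0 + sw.delta2 * max(-x[0], 0.0), "up"),
            Reaction((-1,), lambda x, t: u + sw.delta1 * max(x[0], 0.0), "down"),
        ],
        signed_species=frozenset({"z"}),
    )


def switch_fast_seq_spec(sw: SequestrationSwitch, u: float,
                         a: float = 0.0, b: float = 0.0) -> FastSequestrationSpec:
    """The switch as a fast-sequestration spec (W1 = u0 - delta1*v1,
    W2 = u - delta2*v2); its reduction has drift
    ``u0 - u - delta1*z+ + delta2*z-``."""
    return FastSequestrationSpec(
        W1=lambda t, x, z1, z2: sw.u0 - sw.delta1 * z1,
        W2=lambda t, x, z1, z2: u - sw.delta2 * z2,
        eta=sw.eta_v, a=a, b=b,
    )


def switch_steady_state_closed_form(u: float, u0: float, delta2: float) -> float:
    """Strong-sequestration steady state of V2: ``max(u - u0, 0)/delta2``.

    Piecewise linear with its kink exactly at the threshold ``u = u0``;
    smaller ``delta2`` steepens the post-threshold slope (slope 1/delta2).
    """
    if delta2 <= 0:
        raise ValidationError("delta2 must be positive")
    return max(u - u0, 0.0) / delta2


class _SwitchSystem:
    """Adapter giving switch_rhs the system interface of find_steady_state."""

    state_names = ["v1", "v2"]

    def __init__(self, sw: SequestrationSwitch, u: float) -> None:
        self.rhs = switch_rhs(sw, u)


def sweep_response(sw: SequestrationSwitch, u_grid: Sequence[float],
                   *, tol_abs: float = 1e-9, t_max: float = 1e4) -> pd.DataFrame:
    """Full-ODE steady-state response across an input grid, next to the
    strong-sequestration closed form.

    Returns a frame with columns ``u, v2_full, v2_closed`` plus a
    ``max_gap`` attribute; points that fail to converge are flagged NaN.
    """
    u_grid = list(u_grid)
    if not u_grid:
        raise ValidationError("input grid must be nonempty")
    rows = []
    for u in u_grid:
        res = find_steady_state(_SwitchSystem(sw, u), [0.0, 0.0],
                                tol_abs=tol_abs, t_max=t_max)
        v2 = float(res.state[1]) if res.converged else float("nan")
        rows.append({
            "u": u,
            "v2_full": v2,
            "v2_closed": switch_steady_state_closed_form(u, sw.u0, sw.delta2),
            "converged": res.converged,
        })
    df = pd.DataFrame(rows)
    df.attrs["max_gap"] = float(np.nanmax(np.abs(df.v2_full - df.v2_closed)))
    return df
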