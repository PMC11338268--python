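"""Structured config files (YAML/JSON) for networks, processes and loops.

Reaction rate laws are arithmetic expressions in species names, parameter
names and ``t``, parsed with sympy.  Any parameter may be bound to a
piecewise-constant schedule, in which case the scheduled value replaces
the static one at evaluation time.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import sympy
import yaml

from .crn import Reaction, ReactionNetwork, Schedule, ValidationError
from .controllers import (
    AIFParams,
    ClassicalIFCParams,
    SaturationFunctions,
    aif_loop,
    classical_ifc_loop,
    reduced_aif_loop,
)
from .processes import GeneExpressionProcess, UnimolecularProcess
from .antiwindup import TopologyParams, topology_loop
from .switches import SequestrationSwitch

__all__ = [
    "ConfigError",
    "load_config",
    "schedule_from_config",
    "network_from_config",
    "process_from_config",
    "closed_loop_from_config",
    "switch_from_config",
    "simulation_options",
]


class ConfigError(ValueError):
    """Malformed configuration; the message names the offending key."""


def load_config(path) -> dict:
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise ConfigError(f"cannot parse {path}{where}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return cfg


def _require(cfg: dict, key: str, where: str):
    if key not in cfg:
        raise ConfigError(f"{where}: missing required key {key!r}")
    return cfg[key]


def schedule_from_config(cfg) -> Schedule:
    if isinstance(cfg, (int, float)):
        return Schedule.constant(float(cfg))
    bp = _require(cfg, "breakpoints", "schedule")
    vals = _require(cfg, "values", "schedule")
    return Schedule(tuple(float(b) for b in bp), tuple(float(v) for v in vals))


def network_from_config(cfg: dict) -> ReactionNetwork:
    species = [str(s) for s in _require(cfg, "species", "network")]
    params = {str(k): float(v) for k, v in cfg.get("parameters", {}).items()}
    schedules = {k: schedule_from_config(v) for k, v in cfg.get("schedules", {}).items()}
    for name in schedules:
        if name not in params:
            params[name] = schedules[name](0.0)

    symbols = {name: sympy.Symbol(name) for name in [*species, *params, "t"]}
    args = [symbols["t"]] + [symbols[s] for s in species] + [symbols[p] for p in params]
    param_names = list(params)

    reactions = []
    for i, rc in enumerate(_require(cfg, "reactions", "network")):
        where = f"reactions[{i}]"
        stoich_map = _require(rc, "stoichiometry", where)
        stoich = tuple(int(stoich_map.get(s, 0)) for s in species)
        rate_src = str(_require(rc, "rate", where))
        try:
            expr = sympy.sympify(rate_src, locals=symbols)
        except (sympy.SympifyError, TypeError) as exc:
            raise ConfigError(f"{where}: cannot parse rate {rate_src!r}: {exc}") from exc
        unknown = expr.free_symbols - set(symbols.values())
        if unknown:
            raise ConfigError(f"{where}: unknown symbols {sorted(map(str, unknown))} "
                              f"in rate {rate_src!r}")
        fn = sympy.lambdify(args, expr, modules="numpy")

        def propensity(x, t, _fn=fn):
            pvals = [schedules[p](t) if p in schedules else params[p]
                     for p in param_names]
            return float(_fn(t, *x, *pvals))

        reactions.append(Reaction(stoich, propensity, rc.get("name", f"r{i}")))

    return ReactionNetwork(
        species_names=species, reactions=reactions,
        parameters=params, time_varying=schedules,
    )


def process_from_config(cfg: dict):
    kind = cfg.get("type", "gene_expression")
    if kind == "gene_expression":
        delta = cfg.get("delta", 0.0)
        if isinstance(delta, dict):
            delta = schedule_from_config(delta)
        return GeneExpressionProcess(
            k1=float(cfg.get("k1", 1.0)),
            gamma1=float(cfg.get("gamma1", 1.0)),
            gamma2=float(cfg.get("gamma2", 1.0)),
            delta=delta,
        )
    if kind == "unimolecular":
        return UnimolecularProcess(
            S=np.array(_require(cfg, "S", "process")),
            W=np.array(_require(cfg, "W", "process")),
            b=np.array(_require(cfg, "b", "process")),
        )
    raise ConfigError(f"process: unknown type {kind!r}")


def _sats_from_config(cfg: dict) -> SaturationFunctions:
    ka, ks = cfg.get("kappa_a"), cfg.get("kappa_s")
    from .controllers import hill, identity
    return SaturationFunctions(
        ha=hill(float(ka)) if ka else identity,
        hs=hill(float(ks)) if ks else identity,
    )


def closed_loop_from_config(cfg: dict):
    process = process_from_config(_require(cfg, "process", "config"))
    ctrl = _require(cfg, "controller", "config")
    kind = ctrl.get("type", "aif")
    if kind == "classical_ifc":
        params = ClassicalIFCParams(
            KI=float(_require(ctrl, "KI", "controller")),
            r=float(_require(ctrl, "r", "controller")),
            u_range=tuple(ctrl.get("u_range", (-np.inf, np.inf))),
            y_range=tuple(ctrl.get("y_range", (-np.inf, np.inf))),
        )
        return classical_ifc_loop(process, params)
    if kind in ("aif", "aif_reduced"):
        params = AIFParams(
            mu=float(_require(ctrl, "mu", "controller")),
            theta=float(ctrl.get("theta", 1.0)),
            eta=float(ctrl.get("eta", 100.0)),
            k=float(ctrl.get("k", 1.0)),
            dilution=float(ctrl.get("dilution", 0.0)),
        )
        sats = _sats_from_config(ctrl)
        if kind == "aif_reduced":
            return reduced_aif_loop(process, params, sats)
        aw = ctrl.get("antiwindup")
        if aw:
            top = TopologyParams(
                topology=str(_require(aw, "topology", "antiwindup")),
                aif=params, sats=sats,
                v0=float(aw.get("v0", 10.0)), w0=float(aw.get("w0", 10.0)),
                eta_v=float(aw.get("eta_v", 100.0)),
                eta_w=float(aw.get("eta_w", 100.0)),
                delta_v1=float(aw.get("delta_v1", 1.0)),
                delta_v2=float(aw.get("delta_v2", 1.0)),
                delta_w1=float(aw.get("delta_w1", 1.0)),
                delta_w2=float(aw.get("delta_w2", 1.0)),
                kappa1=float(aw.get("kappa1", 1.0)),
                kappa2=float(aw.get("kappa2", 1.0)),
            )
            return topology_loop(top, process)
        return aif_loop(process, params, sats)
    raise ConfigError(f"controller: unknown type {kind!r}")


def switch_from_config(cfg: dict) -> SequestrationSwitch:
    return SequestrationSwitch(
        u0=float(_require(cfg, "u0", "switch")),
        eta_v=float(_require(cfg, "eta_v", "switch")),
        delta1=float(cfg.get("delta1", 1.0)),
        delta2=float(cfg.get("delta2", 1.0)),
        mode=cfg.get("mode", "activator"),
    )


def simulation_options(cfg: dict) -> dict[str, Any]:
    sim = cfg.get("simulation", {})
    return {
        "t_max": float(sim.get("t_max", 100.0)),
        "rtol": float(sim.get("rtol", 1e-8)),
        "atol": float(sim.get("atol", 1e-10)),
        "method": str(sim.get("method", "BDF")),
        "seed": int(sim.get("seed", 0)),
        "x0": sim.get("x0"),
        "n_points": int(sim.get("n_points", 2001)),
    }
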