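"""YAML configuration loading and result export.

A model config file holds ``geometry``, ``passive``, ``solver`` and
``events`` blocks; a sweep config holds ``grid``, ``protocols`` and
``solver``.  Simulation results export as long-format CSV
(time, position, voltage) plus a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cable import (
    CableGeometry,
    CableModelSpec,
    CurrentClampEvent,
    PassiveProperties,
    ProximalLoad,
    SimulationResult,
    SolverConfig,
    SynapseEvent,
    build_compartments,
    simulate,
)
from .sweep import SWEEP_SOLVER, LibraryGrid


def _geometry_from(block: dict) -> CableGeometry:
    block = dict(block)
    load = block.pop("load", None)
    if load is not None:
        load = ProximalLoad(**load)
    return CableGeometry(load=load, **block)


def load_model_config(path):
    """Read a model config: (spec, events, solver)."""
    cfg = yaml.safe_load(Path(path).read_text())
    geometry = _geometry_from(cfg["geometry"])
    passive = PassiveProperties(**cfg.get("passive", {}))
    solver = SolverConfig(**cfg.get("solver", {}))
    events = []
    for ev in cfg.get("events", []):
        ev = dict(ev)
        kind = ev.pop("type", "synapse")
        if kind == "synapse":
            events.append(SynapseEvent(**ev))
        elif kind == "clamp":
            events.append(CurrentClampEvent(**ev))
        else:
            raise ValueError(f"unknown event type {kind!r}")
    name = cfg.get("name", "")
    return CableModelSpec(geometry=geometry, passive=passive, name=name), \
        events, solver


def load_sweep_config(path):
    """Read a sweep config: (grid, protocols, solver)."""
    cfg = yaml.safe_load(Path(path).read_text())
    grid = LibraryGrid(**cfg.get("grid", {}))
    protocols = tuple(cfg.get("protocols", ("electrotonus", "summation")))
    solver = (SolverConfig(**cfg["solver"]) if "solver" in cfg
              else SWEEP_SOLVER)
    return grid, protocols, solver


def simulate_config(path) -> SimulationResult:
    """Build and run the simulation described by a model config file."""
    spec, events, solver = load_model_config(path)
    chain = build_compartments(spec.geometry, solver)
    synapses = [e for e in events if isinstance(e, SynapseEvent)]
    clamps = [e for e in events if isinstance(e, CurrentClampEvent)]
    return simulate(chain, spec.passive, synapses=synapses, clamps=clamps,
                    solver=solver)


def result_to_csv(result: SimulationResult, path, stride: int = 1) -> None:
    """Write V(t, x) as tidy CSV plus a JSON metadata sidecar."""
    t = result.time[::stride]
    frame = pd.DataFrame({
        "time_ms": np.repeat(t, result.x.size),
        "position_um": np.tile(result.x, t.size),
        "voltage_mV": result.V[::stride].ravel(),
    })
    frame.to_csv(path, index=False)
    Path(path).with_suffix(".meta.json").write_text(
        json.dumps(result.meta, indent=2, default=str))
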