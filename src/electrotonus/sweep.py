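"""Model-library generation and batch protocol runs.

The default library crosses 5 proximal × 4 distal diameters (the full
geometry matrix, endpoints 0.5–20 µm and 0.5–10 µm) with 6 axial
resistivities (10–300 Ω·cm) and 6 membrane resistivities
(10²–2×10⁴ Ω·cm²): 720 models, all 1000 µm long with Cm = 1 µF/cm².
Anti-tapered members (d1 > d0) are legitimate grid members and are
simulated like any other.

``run_sweep`` measures λ_effective and/or the summation statistics for
every member, capturing per-model failures as rows rather than aborting
the batch, and can resume from a partially written CSV.
``taper_comparison`` contrasts gradual (linear) tapers with abrupt step
reductions of the same total diameter drop (default 80%).
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cable import CableGeometry, CableModelSpec, PassiveProperties, SolverConfig
from .protocols import SummationProtocol, run_electrotonus, run_summation

#: coarser integration profile used for batch runs; protocol statistics
#: agree with the cable-core defaults to well under a percent
SWEEP_SOLVER = SolverConfig(dx=4.0, dt=0.05, settle_time=50.0, record_dt=0.5)


@dataclass(frozen=True)
class LibraryGrid:
    d0: Sequence[float] = (0.5, 2.0, 5.0, 10.0, 20.0)
    d1: Sequence[float] = (0.5, 2.0, 5.0, 10.0)
    Ra: Sequence[float] = (10.0, 50.0, 100.0, 150.0, 200.0, 300.0)
    Rm: Sequence[float] = (2e4, 1.6e4, 1e4, 5e3, 1e3, 1e2)
    length: float = 1000.0
    Cm: float = 1.0
    E_leak: float = -50.0

    def __post_init__(self):
        for name in ("d0", "d1", "Ra", "Rm"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"empty grid dimension {name!r}")
            if any(v <= 0 for v in vals):
                raise ValueError(f"grid dimension {name!r} must be positive")

    @property
    def size(self) -> int:
        return len(self.d0) * len(self.d1) * len(self.Ra) * len(self.Rm)


DEFAULT_GRID = LibraryGrid()


def build_library(grid: LibraryGrid = DEFAULT_GRID) -> list:
    """Cartesian product of the grid as CableModelSpec objects."""
    specs = []
    for d0, d1, ra, rm in itertools.product(grid.d0, grid.d1, grid.Ra, grid.Rm):
        profile = "uniform" if d0 == d1 else "linear_taper"
        geom = CableGeometry(d0=d0, d1=d1, length=grid.length, profile=profile)
        pas = PassiveProperties(Ra=ra, Rm=rm, Cm=grid.Cm, E_leak=grid.E_leak)
        specs.append(CableModelSpec(geometry=geom, passive=pas))
    return specs


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _measure(spec: CableModelSpec, protocols, solver, protocol, row):
    # fills `row` in place so statistics computed before a failure survive
    if "electrotonus" in protocols:
        res = run_electrotonus(spec, solver=solver)
        row["lambda_um"] = res.lam.value
        row["lambda_censored"] = res.lam.censored
        row["lambda_bound_um"] = res.lam.lower_bound
    if "summation" in protocols:
        res = run_summation(spec, protocol=protocol, solver=solver)
        row["bias_mvs"] = res.bias
        row["linearity_mvs"] = res.linearity
        row["inward_mvs"] = res.inward_integral
        row["outward_mvs"] = res.outward_integral
        row["arithmetic_sum_mvs"] = res.arithmetic_sum_integral


def run_sweep(library: Sequence[CableModelSpec],
              protocols: Sequence[str] = ("electrotonus", "summation"),
              solver: SolverConfig = SWEEP_SOLVER,
              protocol: Optional[SummationProtocol] = None,
              out: Optional[str] = None,
              resume: bool = True,
              progress: bool = False) -> pd.DataFrame:
    """Run the requested protocols over every library member.

    Per-model failures are recorded in the ``error`` column and the batch
    continues.  With ``out`` set, rows are appended to the CSV as they
    complete and (with ``resume``) models already present are skipped; a
    JSON sidecar records the configuration hash for provenance.
    """
    if len(library) == 0:
        raise ValueError("empty model library")
    unknown = set(protocols) - {"electrotonus", "summation"}
    if unknown:
        raise ValueError(f"unknown protocols: {sorted(unknown)}")

    done = set()
    out_path = Path(out) if out else None
    if out_path is not None and resume and out_path.exists():
        done = set(pd.read_csv(out_path)["model_id"])

    rows = []
    for k, spec in enumerate(library):
        mid = spec.model_id
        if mid in done:
            continue
        g, p = spec.geometry, spec.passive
        row = {"model_id": mid, "d0_um": g.d0, "d1_um": g.d1,
               "profile": g.profile, "length_um": g.length,
               "Ra_ohm_cm": p.Ra, "Rm_ohm_cm2": p.Rm, "error": ""}
        try:
            _measure(spec, protocols, solver, protocol, row)
        except Exception as exc:  # per-row capture keeps the batch alive
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
        if out_path is not None:
            pd.DataFrame([row]).to_csv(out_path, mode="a", index=False,
                                       header=not out_path.exists())
        if progress and (k + 1) % 20 == 0:
            print(f"  {k + 1}/{len(library)} models", flush=True)

    table = pd.DataFrame(rows)
    if out_path is not None:
        sidecar = {
            "config_hash": _config_hash({
                "models": [s.model_id for s in library],
                "protocols": list(protocols),
                "solver": vars(solver) if hasattr(solver, "__dict__")
                          else str(solver),
            }),
            "n_models": len(library),
        }
        out_path.with_suffix(".meta.json").write_text(
            json.dumps(sidecar, indent=2, default=str))
    return table


def taper_comparison(d0_values: Sequence[float] = (1.0, 2.0, 5.0, 10.0),
                     reduction: float = 0.8,
                     step_positions: Sequence[float] = (100.0, 500.0, 900.0),
                     Ra_values: Sequence[float] = (10.0, 50.0, 100.0, 150.0,
                                                   200.0, 300.0),
                     Rm_values: Sequence[float] = (2e4, 1.6e4, 1e4, 5e3,
                                                   1e3, 1e2),
                     length: float = 1000.0,
                     solver: SolverConfig = SWEEP_SOLVER) -> pd.DataFrame:
    """Gradual vs step taper at a fixed fractional diameter reduction.

    For each proximal diameter d0, the distal diameter is
    d1 = (1 − reduction)·d0.  λ_effective is measured for the linear
    taper and for step profiles at each requested position, over the
    passive grid.  One row per (d0, Ra, Rm, profile); step rows carry
    the paired difference to their gradual-taper partner.
    """
    if not (0 < reduction < 1):
        raise ValueError("reduction must be in (0, 1)")
    rows = []
    for d0 in d0_values:
        d1 = (1.0 - reduction) * d0
        for ra in Ra_values:
            for rm in Rm_values:
                pas = PassiveProperties(Ra=ra, Rm=rm)
                variants = [("linear_taper", None,
                             CableGeometry(d0=d0, d1=d1, length=length,
                                           profile="linear_taper"))]
                for sp in step_positions:
                    variants.append(
                        ("step", sp,
                         CableGeometry(d0=d0, d1=d1, length=length,
                                       profile="step", step_position=sp)))
                lam_linear = None
                for profile, sp, geom in variants:
                    res = run_electrotonus(
                        CableModelSpec(geometry=geom, passive=pas),
                        solver=solver)
                    lam_eff = res.lam.effective
                    if profile == "linear_taper":
                        lam_linear = lam_eff
                    rows.append({
                        "d0_um": d0, "d1_um": d1, "Ra_ohm_cm": ra,
                        "Rm_ohm_cm2": rm, "profile": profile,
                        "step_position_um": sp,
                        "lambda_um": res.lam.value,
                        "lambda_censored": res.lam.censored,
                        "lambda_bound_um": res.lam.lower_bound,
                        "lambda_effective_um": lam_eff,
                        "gradual_minus_step_um":
                            None if profile == "linear_taper"
                            else lam_linear - lam_eff,
                    })
    return pd.DataFrame(rows)
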