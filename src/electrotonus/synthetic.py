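"""Synthetic inputs: uncaging datasets, in-silico uncaging experiments,
the packaged per-neuron reversal-potential table, and voxelized tubes.

The statistical generator emulates the structure of site-level uncaging
data: each site responds linearly to the holding potential around a
site-specific reversal potential, ΔV = g·(E_rev − V_m) + ε with Gaussian
amplitude noise, and site distances show no systematic amplitude trend.
The in-silico generator instead runs the cable solver: holding currents
set the recording-site potential, a canonical inhibitory event is evoked
at a distal site, and the signed somatic response feeds the same
reversal-estimation pipeline as experimental data.  Voxelized tapered
tubes with attached skeletons provide ground truth for the morphometry
module.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cable import (
    CableModelSpec,
    CurrentClampEvent,
    SolverConfig,
    build_compartments,
    input_resistance,
    simulate,
)
from .ephys import NeuronDataset, UncagingSite
from .morphology import Skeleton, VoxelVolume
from .protocols import default_synapse

DEFAULT_HOLDING_LEVELS = tuple(np.linspace(-100.0, -40.0, 8))


@dataclass(frozen=True)
class SynthNeuronParams:
    """Generative parameters for one synthetic neuron's uncaging data."""

    cell_type: str = "PD"
    n_sites: int = 20
    distance_range: tuple = (50.0, 1000.0)   # µm
    erev_mean: float = -70.0                  # mV
    erev_sd: float = 3.0                      # between-site SD, mV
    slope_range: tuple = (0.05, 0.2)          # response per mV driving force
    noise_sd: float = 0.2                     # amplitude noise, mV
    holding_levels: tuple = DEFAULT_HOLDING_LEVELS
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if len(self.holding_levels) < 2:
            raise ValueError("need at least two holding levels")


def gen_uncaging_dataset(params: SynthNeuronParams,
                         neuron_id: str = "synth") -> NeuronDataset:
    """Draw a synthetic per-site uncaging dataset (deterministic per seed)."""
    rng = np.random.default_rng(params.seed)
    vm = np.asarray(params.holding_levels, dtype=float)
    sites = []
    for i in range(params.n_sites):
        dist = rng.uniform(*params.distance_range)
        e_rev = rng.normal(params.erev_mean, params.erev_sd)
        g = rng.uniform(*params.slope_range)
        dv = g * (e_rev - vm) + rng.normal(0.0, params.noise_sd, vm.size)
        amp_50 = abs(g * (e_rev - (-50.0))
                     + rng.normal(0.0, params.noise_sd))
        sites.append(UncagingSite(site_id=f"site{i:02d}", distance_um=dist,
                                  vm_mV=vm, dv_mV=dv,
                                  max_amplitude_mV=amp_50,
                                  branch_id=f"b{i % 5}"))
    return NeuronDataset(neuron_id=neuron_id, cell_type=params.cell_type,
                         sites=sites)


def insilico_uncaging(spec: CableModelSpec, site_position: float,
                      holding_levels: Sequence[float] = DEFAULT_HOLDING_LEVELS,
                      solver: Optional[SolverConfig] = None,
                      recording_position: float = 0.0) -> UncagingSite:
    """Simulated uncaging experiment on a cable model.

    For each holding level a constant current at the recording
    compartment brings the local steady-state potential to the target
    (computed exactly from the input resistance — the passive system is
    linear), the canonical inhibitory event is evoked at the site, and
    the signed peak deviation at the recording compartment is the
    response amplitude.  The result plugs straight into
    ``estimate_reversal``.
    """
    solver = solver or SolverConfig(t_end=400.0, settle_time=25.0)
    chain = build_compartments(spec.geometry, solver)
    chain.index_at(site_position)
    r_in = input_resistance(chain, spec.passive, recording_position)
    rec_idx = chain.index_at(recording_position)

    vm = np.asarray(holding_levels, dtype=float)
    dv = np.empty_like(vm)
    for k, target in enumerate(vm):
        i_hold = (target - spec.passive.E_leak) / r_in
        if not math.isfinite(i_hold) or abs(i_hold) > 1e6:
            raise ValueError(f"unreachable holding level {target} mV")
        clamp = CurrentClampEvent(amplitude=i_hold,
                                  position=recording_position,
                                  onset=-math.inf)
        sim = simulate(chain, spec.passive,
                       synapses=[default_synapse(site_position)],
                       clamps=[clamp], solver=solver)
        trace = sim.trace(recording_position)
        base = sim.baseline[rec_idx]
        dev = trace - base
        dv[k] = dev[np.abs(dev).argmax()]

    amp_50 = None
    near_50 = np.isclose(vm, -50.0)
    if near_50.any():
        amp_50 = float(np.abs(dv[near_50]).max())
    return UncagingSite(
        site_id=f"x{site_position:g}",
        distance_um=abs(site_position - recording_position),
        vm_mV=vm, dv_mV=dv, max_amplitude_mV=amp_50)


def _table2_frame() -> pd.DataFrame:
    with resources.files("electrotonus.data").joinpath("table2.csv").open() as f:
        return pd.read_csv(f)


def table2_fixture() -> pd.DataFrame:
    """The packaged per-neuron reversal-potential summary (21 rows).

    Columns: cell type, site count, branch count, mean apparent E_rev
    (mV), SD (mV) and CV, exactly as published; group-average rows are
    excluded (see ``table2_group_expectations``).
    """
    t = _table2_frame()
    out = t[t["is_group_mean"] == 0].drop(columns=["is_group_mean"])
    return out.rename(columns={"neuron": "cell_type"}).reset_index(drop=True)


def table2_group_expectations() -> pd.DataFrame:
    """The published per-cell-type average rows, kept as expected values."""
    t = _table2_frame()
    out = t[t["is_group_mean"] == 1].drop(columns=["is_group_mean"])
    out["cell_type"] = out["neuron"].str.replace("_MEAN", "", regex=False)
    return out.drop(columns=["neuron"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Voxelized tapered tubes (synthetic ground truth for morphometry)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelTubeSpec:
    """A straight (optionally rotated) tube with a known diameter profile.

    ``profile`` is either a (d_proximal, d_distal) pair for a linear
    taper or a callable d(x) in µm.  ``rotation_deg`` rotates the tube
    axis in the x–y plane.  ``jitter_sd`` adds smooth radial surface
    noise (µm).  Voxel size may be isotropic or an (x, y, z) triple,
    mirroring anisotropic confocal sampling.
    """

    profile: Union[tuple, Callable] = (5.0, 5.0)
    length: float = 100.0
    voxel_size: Union[float, tuple] = 0.2
    rotation_deg: float = 0.0
    jitter_sd: float = 0.0
    seed: int = 0
    node_spacing: float = 1.0
    margin: float = 2.0
    shape: Optional[tuple] = None  # forced volume shape (voxels), optional

    def diameter_at(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if callable(self.profile):
            return np.asarray(self.profile(s), dtype=float)
        d0, d1 = self.profile
        return d0 + (d1 - d0) * s / self.length

    @property
    def voxel_triple(self) -> tuple:
        v = self.voxel_size
        if np.isscalar(v):
            return (float(v),) * 3
        return tuple(float(x) for x in v)


@dataclass(frozen=True)
class VoxelTube:
    volume: VoxelVolume
    skeleton: Skeleton
    true_diameter: np.ndarray  # µm, per skeleton node


def gen_voxel_tube(spec: VoxelTubeSpec) -> VoxelTube:
    """Voxelize a tapered tube and its axis skeleton.

    A voxel is set when its center lies within the (jittered) radius of
    the tube axis; skeleton nodes are placed along the axis every
    ``node_spacing`` µm with sequential parent links and ground-truth
    diameters attached.
    """
    vx, vy, vz = spec.voxel_triple
    smax = spec.length
    dmax = float(np.max(spec.diameter_at(np.linspace(0, smax, 64))))
    if np.any(spec.diameter_at(np.linspace(0, smax, 64))
              <= 2 * min(vx, vy, vz)):
        raise ValueError("diameter must exceed two voxels everywhere")

    ang = math.radians(spec.rotation_deg)
    u = np.array([math.cos(ang), math.sin(ang), 0.0])
    r_half = dmax / 2 + spec.margin + 3 * spec.jitter_sd
    p0 = np.array([r_half, r_half, r_half])
    p1 = p0 + u * smax
    hi = np.maximum(p0, p1) + r_half
    shape = spec.shape or (int(math.ceil(hi[0] / vx)),
                           int(math.ceil(hi[1] / vy)),
                           int(math.ceil(hi[2] / vz)))

    # voxel centers at (i + 1/2)·voxel_size
    xs = (np.arange(shape[0]) + 0.5) * vx
    ys = (np.arange(shape[1]) + 0.5) * vy
    zs = (np.arange(shape[2]) + 0.5) * vz
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    rel = np.stack([X - p0[0], Y - p0[1], Z - p0[2]], axis=-1)
    s = rel @ u
    radial = np.linalg.norm(rel - s[..., None] * u, axis=-1)

    rng = np.random.default_rng(spec.seed)
    if spec.jitter_sd > 0:
        # smooth axial jitter: coarse knots every ~5 µm, interpolated
        knots = np.linspace(0, smax, max(3, int(smax / 5)))
        offsets = rng.normal(0.0, spec.jitter_sd, knots.size)
        jitter = np.interp(np.clip(s, 0, smax), knots, offsets)
    else:
        jitter = 0.0
    inside_len = (s >= 0) & (s <= smax)
    radius = spec.diameter_at(np.clip(s, 0, smax)) / 2 + jitter
    mask = inside_len & (radial <= radius)
    if (mask[0].any() or mask[-1].any() or mask[:, 0].any()
            or mask[:, -1].any() or mask[:, :, 0].any()
            or mask[:, :, -1].any()):
        raise ValueError("tube exits volume bounds")

    n_nodes = int(math.floor(smax / spec.node_spacing)) + 1
    svals = np.arange(n_nodes) * spec.node_spacing
    pos = p0[None, :] + svals[:, None] * u[None, :]
    skel = Skeleton(
        ids=np.arange(1, n_nodes + 1),
        xyz=pos,
        parent=np.concatenate([[-1], np.arange(1, n_nodes)]),
    )
    return VoxelTube(volume=VoxelVolume(mask=mask, voxel_size=(vx, vy, vz)),
                     skeleton=skel,
                     true_diameter=spec.diameter_at(svals))
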