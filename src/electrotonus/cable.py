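"""Compartmental model of a single unbranched passive cable.

A cable of arbitrary diameter profile (uniform, linearly tapered, or an
abrupt step) is discretized into cylindrical compartments.  Each
compartment carries a leak conductance and membrane capacitance scaled by
its lateral area; neighbors are coupled by the series combination of
their half-compartment axial conductances, so a diameter step conserves
axial current rather than averaging diameters.  Both cable ends are
sealed (zero axial flux).  An optional proximal load — an equivalent
cylinder attached before x = 0 — models the current sink imposed by the
rest of a neurite tree.

Inputs are conductance synapses with single-exponential decay
g(t) = g_max·exp(−(t−onset)/τ) driving current g·(E_rev − V), and
current-clamp steps.  The membrane equation

    Cm·A_i·dV_i/dt = −(A_i/Rm)·(V_i − E_leak) + Σ_j g_ij·(V_j − V_i)
                     + Σ_s g_s(t)·(E_s − V_i) + I_i(t)

is integrated with the Crank–Nicolson scheme (backward Euler available),
which is unconditionally stable and second-order in time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import solve_banded

from . import units
from ._solver import _integrate

PROFILES = ("uniform", "linear_taper", "step")


@dataclass(frozen=True)
class PassiveProperties:
    """Specific passive membrane constants.

    Ra: axial resistivity, Ω·cm.  Rm: membrane resistivity, Ω·cm².
    Cm: membrane capacitance, µF/cm².  E_leak: leak reversal, mV
    (default −50 mV, the somatic holding potential used experimentally).
    """

    Ra: float = 100.0
    Rm: float = 1e4
    Cm: float = 1.0
    E_leak: float = -50.0

    def __post_init__(self):
        if self.Ra <= 0 or self.Rm <= 0 or self.Cm <= 0:
            raise ValueError("Ra, Rm and Cm must be positive")


@dataclass(frozen=True)
class ProximalLoad:
    """Equivalent cylinder appended proximal to x = 0 (µm)."""

    diameter: float = 20.0
    length: float = 200.0

    def __post_init__(self):
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("load diameter and length must be positive")


@dataclass(frozen=True)
class CableGeometry:
    """Diameter profile of an unbranched cable.

    d0 is the proximal diameter (µm), d1 the distal one.  ``profile`` is
    one of {uniform, linear_taper, step}; a step switches from d0 to d1
    at ``step_position`` (µm from the proximal end).
    """

    d0: float
    d1: float
    length: float = 1000.0
    profile: str = "linear_taper"
    step_position: Optional[float] = None
    load: Optional[ProximalLoad] = None

    def __post_init__(self):
        if self.d0 <= 0 or self.d1 <= 0 or self.length <= 0:
            raise ValueError("diameters and length must be positive")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.profile == "uniform" and self.d0 != self.d1:
            raise ValueError("uniform profile requires d0 == d1")
        if self.profile == "step":
            if self.step_position is None or not (
                0 < self.step_position < self.length
            ):
                raise ValueError("step profile needs 0 < step_position < length")

    @classmethod
    def uniform(cls, diameter: float, length: float = 1000.0,
                load: Optional[ProximalLoad] = None) -> "CableGeometry":
        return cls(d0=diameter, d1=diameter, length=length,
                   profile="uniform", load=load)

    def diameter_at(self, x) -> np.ndarray:
        """Diameter (µm) at position(s) x ∈ [0, length] along the cable."""
        x = np.asarray(x, dtype=float)
        if self.profile == "uniform":
            return np.full_like(x, self.d0)
        if self.profile == "linear_taper":
            return self.d0 + (self.d1 - self.d0) * x / self.length
        return np.where(x < self.step_position, self.d0, self.d1)


@dataclass(frozen=True)
class SynapseEvent:
    """Conductance synapse with instantaneous rise and exponential decay."""

    position: float
    E_rev: float = -75.0
    tau: float = 70.0
    g_max: float = 10.0  # nS
    onset: float = 0.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")
        if self.onset < 0:
            raise ValueError("synapse onset must be >= 0 (post-settle)")


@dataclass(frozen=True)
class CurrentClampEvent:
    """Constant current injection; onset < 0 makes it a holding current
    active throughout the settle period."""

    amplitude: float  # nA
    position: float
    onset: float = 0.0
    duration: float = math.inf


@dataclass(frozen=True)
class SolverConfig:
    dx: float = 2.0            # µm
    dt: float = 0.025          # ms
    t_end: Optional[float] = None
    settle_time: float = 200.0  # ms
    method: str = "crank_nicolson"
    record_dt: float = 0.25    # ms

    def __post_init__(self):
        if self.dx <= 0 or self.dt <= 0 or self.settle_time < 0:
            raise ValueError("dx, dt must be positive; settle_time >= 0")
        if self.method not in ("crank_nicolson", "backward_euler"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def theta(self) -> float:
        return 0.5 if self.method == "crank_nicolson" else 1.0


@dataclass(frozen=True)
class CompartmentChain:
    """Discretized cable: per-compartment centers (µm; negative in the
    proximal load), widths, diameters and membrane areas, plus the purely
    geometric part of the inter-compartment axial coupling."""

    x: np.ndarray          # centers, strictly increasing
    width: np.ndarray      # µm
    diam: np.ndarray       # µm
    area_cm2: np.ndarray
    axial_factor: np.ndarray  # cm; g_ij = factor/Ra in S
    n_load: int
    length: float

    @property
    def n(self) -> int:
        return self.x.size

    def axial_conductance_uS(self, Ra: float) -> np.ndarray:
        """Inter-compartment axial conductances (µS) for resistivity Ra."""
        return self.axial_factor / Ra * 1e6

    def index_at(self, position: float) -> int:
        """Index of the compartment whose center is nearest ``position``."""
        lo = self.x[0] - self.width[0] / 2
        if not (lo - 1e-9 <= position <= self.length + 1e-9):
            raise ValueError(
                f"position {position} µm is off the cable "
                f"([{lo:.1f}, {self.length:.1f}] µm)"
            )
        return int(np.argmin(np.abs(self.x - position)))


@dataclass(frozen=True)
class SimulationResult:
    """Membrane-potential matrix V(t, x) with its grids and baseline.

    ``time`` (ms) starts at 0 = end of the settle period; ``baseline`` is
    the potential profile at that instant.  ``meta`` records the event
    count, geometry and solver settings for provenance.
    """

    time: np.ndarray
    x: np.ndarray
    V: np.ndarray          # shape (len(time), len(x)), mV
    baseline: np.ndarray   # mV, per position
    meta: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return self.meta.get("n_synapses", 0) + self.meta.get("n_clamps", 0)

    def trace(self, position: float) -> np.ndarray:
        """Voltage time course at the compartment nearest ``position``."""
        i = int(np.argmin(np.abs(self.x - position)))
        return self.V[:, i]


def build_compartments(geometry: CableGeometry,
                       solver: SolverConfig) -> CompartmentChain:
    """Discretize ``geometry`` into compartments of width ≈ solver.dx.

    The main cable is split into round(length/dx) equal compartments and
    the diameter profile is evaluated at compartment centers.  A proximal
    load contributes additional compartments at negative positions.
    """
    if solver.dx > geometry.length:
        raise ValueError("degenerate discretization: dx exceeds cable length")
    n_main = int(round(geometry.length / solver.dx))
    w_main = geometry.length / n_main
    x_main = (np.arange(n_main) + 0.5) * w_main
    d_main = geometry.diameter_at(x_main)

    if geometry.load is not None:
        load = geometry.load
        n_load = max(1, int(round(load.length / solver.dx)))
        w_load = load.length / n_load
        x_load = -load.length + (np.arange(n_load) + 0.5) * w_load
        x = np.concatenate([x_load, x_main])
        w = np.concatenate([np.full(n_load, w_load), np.full(n_main, w_main)])
        d = np.concatenate([np.full(n_load, load.diameter), d_main])
    else:
        n_load = 0
        x, w, d = x_main, np.full(n_main, w_main), d_main

    area = units.lateral_area_cm2(d, w)
    # series half-compartment conductances across each interior face
    g_half = (np.pi * d**2 / 4.0 * units.UM2_TO_CM2) / (w / 2.0 * units.UM_TO_CM)
    factor = 1.0 / (1.0 / g_half[:-1] + 1.0 / g_half[1:])  # g·Ra, units: cm
    return CompartmentChain(x=x, width=w, diam=d, area_cm2=area,
                            axial_factor=factor, n_load=n_load,
                            length=geometry.length)


def _conductance_matrix(chain: CompartmentChain, passive: PassiveProperties):
    """Leak + axial conductance arrays (µS): (gL, a)."""
    gL = units.leak_conductance_uS(passive.Rm, chain.area_cm2)
    a = chain.axial_conductance_uS(passive.Ra)
    return gL, a


def steady_state(chain: CompartmentChain, passive: PassiveProperties,
                 currents: Sequence[tuple] = ()) -> np.ndarray:
    """Exact steady-state voltage profile (mV) under constant currents.

    ``currents`` is a sequence of (position µm, amplitude nA) pairs.  The
    steady system G·V = b is tridiagonal and solved directly.
    """
    gL, a = _conductance_matrix(chain, passive)
    n = chain.n
    diag = gL.copy()
    diag[:-1] += a
    diag[1:] += a
    ab = np.zeros((3, n))
    ab[0, 1:] = -a
    ab[1] = diag
    ab[2, :-1] = -a
    b = gL * passive.E_leak
    for pos, amp in currents:
        b[chain.index_at(pos)] += amp
    return solve_banded((1, 1), ab, b)


def input_resistance(chain: CompartmentChain, passive: PassiveProperties,
                     position: float) -> float:
    """Steady-state input resistance ΔV/ΔI (MΩ) at ``position``."""
    i_test = 1.0  # nA; the system is linear, so the magnitude is arbitrary
    v = steady_state(chain, passive, [(position, i_test)])
    return float((v[chain.index_at(position)] - passive.E_leak) / i_test)


def transfer_resistance(chain: CompartmentChain, passive: PassiveProperties,
                        inject_at: float, record_at: float) -> float:
    """Steady-state transfer resistance (MΩ): ΔV at record per nA injected."""
    v = steady_state(chain, passive, [(inject_at, 1.0)])
    return float(v[chain.index_at(record_at)] - passive.E_leak)


def simulate(chain: CompartmentChain, passive: PassiveProperties,
             synapses: Sequence[SynapseEvent] = (),
             clamps: Sequence[CurrentClampEvent] = (),
             solver: SolverConfig = SolverConfig(t_end=400.0)) -> SimulationResult:
    """Integrate the cable equation and return the recorded voltage matrix.

    Holding clamps (onset < 0) are active during the settle period and
    the initial state is the exact steady state under them, so the
    baseline at t = 0 is fully converged.  Event positions must lie on
    the chain (the proximal load is addressable at negative positions).
    """
    if solver.t_end is None or solver.t_end <= 0:
        raise ValueError("solver.t_end must be set and positive")

    gL, a = _conductance_matrix(chain, passive)
    C = units.membrane_capacitance_nF(passive.Cm, chain.area_cm2)
    C_dt = C / solver.dt

    def snap(t):
        # onsets snapped to the time grid as single products of dt, making
        # activation comparisons inside the kernel exact
        if not math.isfinite(t) or abs(t) >= 1e29:
            return math.copysign(1e30, t)
        return round(t / solver.dt) * solver.dt

    syn_idx = np.array([chain.index_at(s.position) for s in synapses], dtype=np.int64)
    syn_g = np.array([s.g_max * units.NS_TO_US for s in synapses])
    syn_tau = np.array([s.tau for s in synapses])
    syn_onset = np.array([snap(s.onset) for s in synapses])
    syn_erev = np.array([s.E_rev for s in synapses])

    cl_idx = np.array([chain.index_at(c.position) for c in clamps], dtype=np.int64)
    cl_amp = np.array([c.amplitude for c in clamps])
    def clamp_end(c):
        end = c.onset + c.duration
        if math.isnan(end) or end >= 1e29:  # -inf onset + inf duration
            return 1e30
        return snap(end)

    cl_onset = np.array([snap(c.onset) if c.onset >= 0 else -1e30
                         for c in clamps])
    cl_end = np.array([clamp_end(c) for c in clamps])

    holding = [(c.position, c.amplitude) for c in clamps if c.onset < 0]
    V0 = steady_state(chain, passive, holding)

    rec_every = max(1, int(round(solver.record_dt / solver.dt)))
    n_main = int(math.ceil(round(solver.t_end / solver.dt) / rec_every)) * rec_every
    n_settle = int(round(solver.settle_time / solver.dt))
    n_rec = n_main // rec_every + 1

    out = np.empty((n_rec, chain.n))
    status = _integrate(V0.copy(), C_dt, gL, a, passive.E_leak,
                        syn_idx, syn_g, syn_tau, syn_onset, syn_erev,
                        cl_idx, cl_amp, cl_onset, cl_end,
                        solver.dt, n_settle, n_main, solver.theta,
                        rec_every, out)
    if status >= 0:
        raise RuntimeError(f"solver divergence at step {status}")

    time = np.arange(n_rec) * rec_every * solver.dt
    meta = {
        "n_synapses": len(synapses),
        "n_clamps": len(clamps),
        "synapse_positions": [s.position for s in synapses],
        "clamp_positions": [c.position for c in clamps],
        "E_leak": passive.E_leak,
        "solver": {"dx": solver.dx, "dt": solver.dt, "t_end": solver.t_end,
                   "settle_time": solver.settle_time, "method": solver.method,
                   "record_dt": solver.record_dt},
        "load": None if chain.n_load == 0 else
                {"n_compartments": chain.n_load},
    }
    return SimulationResult(time=time, x=chain.x.copy(), V=out,
                            baseline=out[0].copy(), meta=meta)


@dataclass(frozen=True)
class CableModelSpec:
    """One member of the model library: geometry plus passive properties."""

    geometry: CableGeometry
    passive: PassiveProperties
    name: str = ""

    @property
    def model_id(self) -> str:
        g, p = self.geometry, self.passive
        base = (f"d0={g.d0:g}_d1={g.d1:g}_{g.profile}"
                f"_Ra={p.Ra:g}_Rm={p.Rm:g}")
        if g.profile == "step":
            base += f"_at{g.step_position:g}"
        if g.load is not None:
            base += f"_load{g.load.diameter:g}x{g.load.length:g}"
        return base
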