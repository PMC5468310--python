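"""Transient and steady-state solution of the field-coupled cable system.

A uniform extracellular field enters the cable equation only through the
extracellular potential differences between adjacent compartment centers:
the axial current between neighbors j, k is
g_jk * ((V_k + V_ext,k) - (V_j + V_ext,j)), so the field acts as the drive
term L·V_ext (L the axial-conductance Laplacian) on the transmembrane
system. Only differences of V_ext matter; the dynamics are invariant to
adding any constant (the reference/"cathode ground" choice is cosmetic).

Transverse field coupling is deliberately absent: polarization is driven
exclusively by the axial gradient of V_ext, following the standard
assumption that membranes are insensitive to the transverse component.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .biophysics import Biophysics, MembraneState
from .errors import (InitializationError, ParameterError, SolverDivergenceError,
                     SuprathresholdFieldError)
from .kinetics import TABLE_DV, TABLE_V_MIN
from .morphology import MorphologyTree
from .system import CompartmentalSystem, axial_conductance, build_system

__all__ = [
    "FieldStimulus", "CurrentInjection", "SolverConfig", "Trace",
    "axial_conductance", "build_system", "extracellular_potentials",
    "field_drive", "simulate", "simulate_system", "init_steady_state",
    "init_system_steady_state", "steady_state_polarization",
    "PolarizationResult",
]


@dataclass(frozen=True)
class FieldStimulus:
    """Uniform extracellular field step.

    amplitude: mV/mm, signed -- positive places the anode on the dendritic
    (+y) side and the cathode near the axon. angle: degrees between the
    field and the +y axis (0 for every experiment of record). onset/offset
    in ms; default 100 ms baseline then 500 ms of field.
    """

    amplitude: float
    angle: float = 0.0
    onset: float = 100.0
    offset: float = 600.0

    def __post_init__(self):
        if not self.offset > self.onset:
            raise ParameterError("field offset must exceed onset")


@dataclass(frozen=True)
class CurrentInjection:
    """Rectangular intracellular current pulse at a point site (nA)."""

    section: str
    amplitude: float
    arc: float = 0.5
    onset: float = 100.0
    offset: float = 600.0

    def __post_init__(self):
        if not self.offset > self.onset:
            raise ParameterError("injection offset must exceed onset")


Stimulus = Union[FieldStimulus, CurrentInjection]


@dataclass(frozen=True)
class SolverConfig:
    """Integration settings.

    dt in ms (first-order implicit step); max_compartment_length in μm (odd
    compartment counts per section so midpoints exist); record_sites is a
    list of (section, arc) pairs or "all"; steady_state_tolerance is the
    settling criterion max|dV/dt| in mV/ms.
    """

    dt: float = 0.025
    max_compartment_length: float = 10.0
    record_sites: object = (("soma", 0.5),)
    duration: Optional[float] = None
    steady_state_tolerance: float = 1e-5
    record_every: int = 1
    init_time_budget: float = 5000.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.max_compartment_length <= 0:
            raise ParameterError("max_compartment_length must be > 0")
        if self.duration is not None and self.duration <= 0:
            raise ParameterError("duration must be > 0")


@dataclass
class Trace:
    """Recorded transmembrane voltage per site over time."""

    times: np.ndarray                # ms, strictly increasing
    sites: list                      # (section, arc) per row of V
    V: np.ndarray                    # (n_sites, n_times) mV
    v_ext: Optional[np.ndarray] = None  # optional per-site V_ext (constant), mV

    def site(self, section: str, arc: Optional[float] = None) -> np.ndarray:
        matches = [i for i, (s, a) in enumerate(self.sites)
                   if s == section and (arc is None or abs(a - arc) < 1e-9)]
        if not matches:
            raise ParameterError(f"site ({section!r}, {arc}) was not recorded")
        best = matches[0] if arc is None else min(
            matches, key=lambda i: abs(self.sites[i][1] - (arc or 0.0)))
        return self.V[best]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (sec, arc) in enumerate(self.sites):
            rows.append(pd.DataFrame({"time_ms": self.times, "section": sec,
                                      "arc": arc, "v_mV": self.V[i]}))
        return pd.concat(rows, ignore_index=True)[["time_ms", "section", "arc", "v_mV"]]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("V", data=self.V)
            sec = np.array([s for s, _ in self.sites], dtype="S64")
            arc = np.array([a for _, a in self.sites])
            f.create_dataset("site_section", data=sec)
            f.create_dataset("site_arc", data=arc)
            if self.v_ext is not None:
                f.create_dataset("v_ext", data=self.v_ext)

    @classmethod
    def from_hdf5(cls, path) -> "Trace":
        import h5py
        with h5py.File(path, "r") as f:
            sites = [(s.decode(), float(a)) for s, a in
                     zip(f["site_section"][:], f["site_arc"][:])]
            v_ext = f["v_ext"][:] if "v_ext" in f else None
            return cls(times=f["times"][:], sites=sites, V=f["V"][:], v_ext=v_ext)


# ---------------------------------------------------------------------------
# field coupling
# ---------------------------------------------------------------------------

def extracellular_potentials(system: CompartmentalSystem, amplitude: float,
                             angle: float = 0.0) -> np.ndarray:
    """Per-compartment V_ext (mV) for a uniform field (mV/mm).

    The potential grows along the field direction toward the anode; the
    reference (cathode) plane is placed at the field-projection minimum of
    the morphology so stored values are reproducible. Only differences of
    V_ext enter the dynamics.
    """
    if amplitude == 0.0:
        return np.zeros(system.n)
    a = math.radians(angle)
    proj_um = system.y * math.cos(a) + system.x * math.sin(a)
    signed = amplitude * proj_um / 1000.0            # mV/mm · μm -> mV
    return signed - signed.min()


def field_drive(system: CompartmentalSystem, v_ext: np.ndarray) -> np.ndarray:
    """RHS drive (nA) produced by an extracellular potential profile."""
    return system.laplacian_apply(v_ext)


def _steps(t_ms: float, dt: float) -> int:
    return int(round(t_ms / dt))


def _prepare_drives(system: CompartmentalSystem, stimuli: Sequence[Stimulus],
                    dt: float):
    drives, on, off = [], [], []
    for stim in stimuli:
        if isinstance(stim, FieldStimulus):
            v_ext = extracellular_potentials(system, stim.amplitude, stim.angle)
            drives.append(field_drive(system, v_ext))
        elif isinstance(stim, CurrentInjection):
            vec = np.zeros(system.n)
            vec[system.comp_index(stim.section, stim.arc)] = stim.amplitude
            drives.append(vec)
        else:
            raise ParameterError(f"unsupported stimulus {type(stim).__name__}")
        on.append(_steps(stim.onset, dt))
        off.append(_steps(stim.offset, dt))
    if not drives:
        return (np.zeros((0, system.n)), np.zeros(0, dtype=np.int64),
                np.zeros(0, dtype=np.int64))
    return (np.asarray(drives), np.asarray(on, dtype=np.int64),
            np.asarray(off, dtype=np.int64))


def _resolve_record(system: CompartmentalSystem, record_sites):
    if isinstance(record_sites, str) and record_sites == "all":
        idx = np.arange(system.n, dtype=np.int64)
        sites = system.all_sites()
        return idx, sites
    idx, sites = [], []
    for sec, arc in record_sites:
        i = system.comp_index(sec, arc)
        idx.append(i)
        sites.append((system.section_id[i], float(system.arc[i])))
    return np.asarray(idx, dtype=np.int64), sites


def _pack_state(system: CompartmentalSystem, state: Optional[MembraneState]):
    if state is None:
        v = np.full(system.n, system.e_leak)
        gates = system.resting_gates(v)
        return v, gates
    v = np.array(state.V, dtype=float, copy=True)
    ngate = len(system.gate_names)
    gates = np.empty((ngate, system.n))
    for g, name in enumerate(system.gate_names):
        gates[g] = state.gates[name]
    return v, gates


def _unpack_state(system: CompartmentalSystem, v: np.ndarray,
                  gates: np.ndarray) -> MembraneState:
    return MembraneState(V=v.copy(), gates={name: gates[g].copy()
                                            for g, name in enumerate(system.gate_names)})


def _run(system: CompartmentalSystem, v, gates, nsteps, dt, drives, on, off,
         rec_idx, rec_every, compute_resid=False):
    from ._kernel import run_steps
    nrec = rec_idx.shape[0]
    ncols = nsteps // rec_every + 1
    rec_out = np.empty((nrec, ncols))
    etau = np.exp(-dt / system.tau_tab) if system.tau_tab.size else \
        np.ones_like(system.tau_tab)
    status, err_step, err_comp, max_resid, last_delta = run_steps(
        v, gates, nsteps, dt,
        system.parent, system.g_ax, system.C, system.g_leak, system.e_leak,
        system.chan_g, system.chan_E, system.gate_chan, system.gate_exp,
        system.inf_tab, etau, TABLE_V_MIN, TABLE_DV,
        drives, on, off, rec_idx, rec_every, rec_out, compute_resid)
    if status != 0:
        t = err_step * dt
        site = (system.section_id[err_comp], float(system.arc[err_comp]))
        raise SolverDivergenceError(
            f"membrane potential diverged at t = {t:.3f} ms, site {site}",
            time_ms=t, site=site)
    return rec_out, max_resid, last_delta


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def init_system_steady_state(system: CompartmentalSystem,
                             config: SolverConfig = SolverConfig()) -> MembraneState:
    """Relax the unstimulated system to rest.

    Passive membranes rest exactly at E_leak (the unique fixed point).
    Active membranes are relaxed by simulation in chunks until the largest
    per-compartment |dV/dt| falls below the configured tolerance.
    """
    if system.biophys.is_passive:
        v = np.full(system.n, system.e_leak)
        return _unpack_state(system, v, np.zeros((0, system.n)))
    v = np.full(system.n, system.e_leak)
    gates = system.resting_gates(v)
    dt = max(config.dt, 0.025)
    chunk = _steps(100.0, dt)
    no_drive = (np.zeros((0, system.n)), np.zeros(0, dtype=np.int64),
                np.zeros(0, dtype=np.int64))
    rec_idx = np.zeros(1, dtype=np.int64)
    elapsed = 0.0
    last_delta = math.inf
    while elapsed < config.init_time_budget:
        _, _, last_delta = _run(system, v, gates, chunk, dt, *no_drive,
                                rec_idx=rec_idx, rec_every=chunk)
        elapsed += chunk * dt
        if last_delta / dt < config.steady_state_tolerance:
            return _unpack_state(system, v, gates)
    raise InitializationError(
        f"no steady state within {config.init_time_budget:.0f} ms "
        f"(residual {last_delta / dt:.3e} mV/ms)", residual=last_delta / dt)


def init_steady_state(tree: MorphologyTree, biophys: Biophysics,
                      config: SolverConfig = SolverConfig()) -> MembraneState:
    system = build_system(tree, biophys, config.max_compartment_length)
    return init_system_steady_state(system, config)


def simulate_system(system: CompartmentalSystem, stimuli: Sequence[Stimulus],
                    config: SolverConfig = SolverConfig(),
                    state: Optional[MembraneState] = None,
                    return_state: bool = False,
                    compute_residual: bool = False):
    """Advance the system and return a Trace (optionally with final state).

    ``state`` defaults to the relaxed resting state (computed on the fly).
    """
    if state is None:
        state = init_system_steady_state(system, config)
    v, gates = _pack_state(system, state)
    dt = config.dt
    duration = config.duration
    if duration is None:
        duration = max((s.offset for s in stimuli), default=0.0) + 100.0
    nsteps = _steps(duration, dt)
    drives, on, off = _prepare_drives(system, stimuli, dt)
    rec_idx, sites = _resolve_record(system, config.record_sites)
    rec_out, max_resid, _ = _run(system, v, gates, nsteps, dt, drives, on, off,
                                 rec_idx, config.record_every,
                                 compute_resid=compute_residual)
    times = dt * config.record_every * np.arange(rec_out.shape[1])
    v_ext = None
    for stim in stimuli:
        if isinstance(stim, FieldStimulus) and stim.amplitude != 0.0:
            full = extracellular_potentials(system, stim.amplitude, stim.angle)
            v_ext = full[rec_idx]
            break
    trace = Trace(times=times, sites=sites, V=rec_out, v_ext=v_ext)
    out = [trace]
    if return_state:
        out.append(_unpack_state(system, v, gates))
    if compute_residual:
        out.append(max_resid)
    return trace if len(out) == 1 else tuple(out)


def simulate(tree: MorphologyTree, biophys: Biophysics,
             stimuli: Sequence[Stimulus],
             config: SolverConfig = SolverConfig(),
             state: Optional[MembraneState] = None) -> Trace:
    """Build, (optionally) initialize and integrate in one call."""
    system = build_system(tree, biophys, config.max_compartment_length)
    return simulate_system(system, stimuli, config, state=state)


@dataclass
class PolarizationResult:
    """Steady-state field-induced polarization ΔV per compartment."""

    sites: list                 # (section, arc)
    y: np.ndarray               # μm, compartment centers
    delta_v: np.ndarray         # mV
    amplitude: float            # mV/mm
    soma_delta_v: float         # mV at the soma midpoint

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "section": [s for s, _ in self.sites],
            "arc": [a for _, a in self.sites],
            "y_um": self.y, "delta_v_mV": self.delta_v,
        })


def steady_state_polarization(tree: MorphologyTree, biophys: Biophysics,
                              amplitude: float,
                              config: SolverConfig = SolverConfig(),
                              system: Optional[CompartmentalSystem] = None,
                              state: Optional[MembraneState] = None,
                              max_settle_ms: float = 2000.0) -> PolarizationResult:
    """Settled ΔV = V(field on) - V(rest) for a subthreshold field.

    Raises SuprathresholdFieldError if the field evokes a spike (any
    compartment crossing 0 mV) during settling.
    """
    if system is None:
        system = build_system(tree, biophys, config.max_compartment_length)
    if state is None:
        state = init_system_steady_state(system, config)
    v0 = np.asarray(state.V, dtype=float).copy()
    v, gates = _pack_state(system, state)
    dt = config.dt
    v_ext = extracellular_potentials(system, amplitude)
    drives = field_drive(system, v_ext)[None, :]
    chunk = _steps(100.0, dt)
    on = np.zeros(1, dtype=np.int64)
    off = np.full(1, chunk + 1, dtype=np.int64)
    rec_idx = np.arange(system.n, dtype=np.int64)
    elapsed = 0.0
    while True:
        rec_out, _, last_delta = _run(system, v, gates, chunk, dt, drives, on, off,
                                      rec_idx, rec_every=1)
        if rec_out.max() > 0.0:
            raise SuprathresholdFieldError(
                f"field {amplitude} mV/mm evoked a spike during settling")
        elapsed += chunk * dt
        if last_delta / dt < config.steady_state_tolerance:
            break
        if elapsed >= max_settle_ms:
            raise InitializationError(
                f"polarization did not settle within {max_settle_ms:.0f} ms",
                residual=last_delta / dt)
    delta = v - v0
    soma = system.comp_index("soma", 0.5)
    return PolarizationResult(sites=system.all_sites(), y=system.y.copy(),
                              delta_v=delta, amplitude=amplitude,
                              soma_delta_v=float(delta[soma]))
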