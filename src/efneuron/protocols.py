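"""Experiment protocols: spike detection, threshold search, sweeps, f-E
curves, EPSC co-stimulation, AP-site diagnostics and polarization summaries.

The central quantity is the field firing threshold (field rheobase): the
minimal uniform-field amplitude that evokes at least one somatic action
potential, located by a coarse upward scan followed by bisection. Every
protocol is a pure, deterministic function of its configuration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .biophysics import Biophysics
from .errors import ParameterError
from .field_solver import (CurrentInjection, FieldStimulus, SolverConfig, Trace,
                           build_system, init_system_steady_state,
                           simulate_system, steady_state_polarization)
from .morphology import ArtificialNeuronParams, MorphologyTree, build_artificial_neuron

#: spike detector defaults: upward crossing of 0 mV, 2 ms refractory
DETECTION_THRESHOLD_MV = 0.0
REFRACTORY_MS = 2.0


@dataclass(frozen=True)
class SpikeTrain:
    spike_times: np.ndarray          # ms, strictly increasing
    detection_threshold: float
    refractory: float

    def __len__(self) -> int:
        return len(self.spike_times)


def detect_spikes(trace: Trace, site=("soma", 0.5),
                  threshold_mV: float = DETECTION_THRESHOLD_MV,
                  refractory_ms: float = REFRACTORY_MS) -> SpikeTrain:
    """Times of upward threshold crossings separated by the refractory gap."""
    v = trace.site(*site)
    t = trace.times
    above = v >= threshold_mV
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    last = -math.inf
    for i in crossings:
        if t[i] - last >= refractory_ms:
            times.append(t[i])
            last = t[i]
    return SpikeTrain(np.asarray(times), threshold_mV, refractory_ms)


def firing_rate(spikes: SpikeTrain, window: tuple[float, float]) -> float:
    """Mean rate (Hz) of spikes falling inside [w0, w1] (ms)."""
    w0, w1 = window
    if not w1 > w0:
        raise ParameterError("firing-rate window must have positive length")
    n = int(np.count_nonzero((spikes.spike_times >= w0) & (spikes.spike_times <= w1)))
    return n / (w1 - w0) * 1000.0


# ---------------------------------------------------------------------------
# threshold search
# ---------------------------------------------------------------------------

#: EPSC defaults: a brief pulse arriving after the field-driven
#: depolarization has developed. A sustained pulse would not stay
#: subthreshold: the artificial cell's input resistance is of order GΩ, so
#: even 0.01 nA held indefinitely spikes the cell on its own; a few-ms pulse
#: is charge-limited to a physiological EPSP-sized depolarization.
EPSC_DELAY_MS = 50.0
EPSC_DURATION_MS = 2.0


@dataclass(frozen=True)
class EPSCStimulus:
    """Brief rectangular depolarizing current pulse emulating an EPSC.

    Injected into a distal dendrite (No. 8 by default); by default it
    arrives ``EPSC_DELAY_MS`` after field onset and lasts
    ``EPSC_DURATION_MS``. Must be subthreshold on its own.
    """

    target_section: str = "dend8"
    amplitude: float = 0.01          # nA
    onset: Optional[float] = None    # ms; None -> field onset + EPSC_DELAY_MS
    duration: float = EPSC_DURATION_MS  # ms

    def __post_init__(self):
        if self.amplitude < 0:
            raise ParameterError("EPSC amplitude must be >= 0")
        if not self.duration > 0:
            raise ParameterError("EPSC duration must be > 0")


@dataclass(frozen=True)
class ThresholdResult:
    polarity: str                    # '+' or '-'
    E_threshold: Optional[float]     # mV/mm, signed; None if none <= E_max
    resolution: float
    bracket: Optional[tuple]         # (E_no_spike, E_spike), signed
    search_log: tuple                # ((E, spike_count), ...)
    E_max: float

    @property
    def found(self) -> bool:
        return self.E_threshold is not None


def _polarity_sign(polarity) -> tuple[str, float]:
    if polarity in ("+", "positive", 1, +1.0):
        return "+", 1.0
    if polarity in ("-", "negative", -1, -1.0):
        return "-", -1.0
    raise ParameterError(f"polarity must be '+' or '-', got {polarity!r}")


def _threshold_search(system, state, sign: str, sgn: float, E_max: float,
                      resolution: float, coarse_step: float,
                      config: SolverConfig, onset: float, offset: float,
                      extra_stimuli: Sequence = ()) -> ThresholdResult:
    run_cfg = replace(config, record_sites=(("soma", 0.5),),
                      duration=offset + 50.0)

    def spike_count(E: float) -> int:
        stims = list(extra_stimuli)
        if E != 0.0:
            stims.insert(0, FieldStimulus(sgn * E, onset=onset, offset=offset))
        trace = simulate_system(system, stims, run_cfg, state=state)
        st = detect_spikes(trace)
        return int(np.count_nonzero((st.spike_times >= onset)
                                    & (st.spike_times <= offset + 25.0)))

    log = []
    n0 = spike_count(0.0)
    log.append((0.0, n0))
    if n0 > 0:
        raise ParameterError("neuron is not quiescent without a field")

    lo, hi = 0.0, None
    k = 1
    while True:
        E = k * coarse_step
        if E > E_max + 1e-9:
            break
        n = spike_count(E)
        log.append((sgn * E, n))
        if n > 0:
            hi = E
            break
        lo = E
        k += 1
    if hi is None:
        return ThresholdResult(sign, None, resolution, None, tuple(log), E_max)

    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        n = spike_count(mid)
        log.append((sgn * mid, n))
        if n > 0:
            hi = mid
        else:
            lo = mid
    return ThresholdResult(sign, sgn * hi, resolution, (sgn * lo, sgn * hi),
                           tuple(log), E_max)


def _epsc_to_injection(epsc: EPSCStimulus, onset: float, offset: float) -> CurrentInjection:
    e_on = epsc.onset if epsc.onset is not None else onset + EPSC_DELAY_MS
    return CurrentInjection(section=epsc.target_section, amplitude=epsc.amplitude,
                            arc=0.5, onset=e_on, offset=e_on + epsc.duration)


def find_EF_threshold(tree: MorphologyTree, biophys: Biophysics,
                      polarity="+", E_max: float = 1000.0,
                      resolution: float = 0.5, coarse_step: float = 10.0,
                      config: SolverConfig = SolverConfig(),
                      field_onset: float = 100.0,
                      field_offset: float = 600.0) -> ThresholdResult:
    """Minimal field amplitude evoking a somatic AP, to ``resolution``."""
    sign, sgn = _polarity_sign(polarity)
    system = build_system(tree, biophys, config.max_compartment_length)
    state = init_system_steady_state(system, config)
    return _threshold_search(system, state, sign, sgn, E_max, resolution,
                             coarse_step, config, field_onset, field_offset)


def threshold_with_epsc(tree: MorphologyTree, biophys: Biophysics,
                        epsc: EPSCStimulus, polarity="+",
                        E_max: float = 1000.0, resolution: float = 0.5,
                        coarse_step: float = 10.0,
                        config: SolverConfig = SolverConfig(),
                        field_onset: float = 100.0,
                        field_offset: float = 600.0) -> ThresholdResult:
    """Field threshold with a subthreshold EPSC co-applied."""
    sign, sgn = _polarity_sign(polarity)
    system = build_system(tree, biophys, config.max_compartment_length)
    state = init_system_steady_state(system, config)
    inj = _epsc_to_injection(epsc, field_onset, field_offset)
    if epsc.amplitude > 0:
        probe_cfg = replace(config, record_sites=(("soma", 0.5),),
                            duration=inj.offset + 50.0)
        trace = simulate_system(system, [inj], probe_cfg, state=state)
        if len(detect_spikes(trace)) > 0:
            raise ParameterError("EPSC alone evokes a spike; it must be subthreshold")
    extra = [inj] if epsc.amplitude > 0 else []
    return _threshold_search(system, state, sign, sgn, E_max, resolution,
                             coarse_step, config, field_onset, field_offset,
                             extra_stimuli=extra)


# ---------------------------------------------------------------------------
# f-E curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FECurve:
    E: np.ndarray                    # mV/mm (signed)
    f: np.ndarray                    # Hz over the field-on window
    window: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"E_mV_per_mm": self.E, "f_Hz": self.f})


def f_E_curve(tree: MorphologyTree, biophys: Biophysics, E_grid,
              config: SolverConfig = SolverConfig(),
              field_onset: float = 100.0, field_offset: float = 600.0) -> FECurve:
    """Somatic firing rate versus field amplitude over the field-on window."""
    E_grid = np.asarray(sorted(E_grid), dtype=float)
    system = build_system(tree, biophys, config.max_compartment_length)
    state = init_system_steady_state(system, config)
    run_cfg = replace(config, record_sites=(("soma", 0.5),),
                      duration=field_offset + 50.0)
    rates = []
    for E in E_grid:
        stims = [FieldStimulus(E, onset=field_onset, offset=field_offset)] if E else []
        trace = simulate_system(system, stims, run_cfg, state=state)
        rates.append(firing_rate(detect_spikes(trace), (field_onset, field_offset)))
    return FECurve(E_grid, np.asarray(rates), (field_onset, field_offset))


# ---------------------------------------------------------------------------
# morphology sweeps
# ---------------------------------------------------------------------------

SWEEPABLE = ("soma_diameter", "soma_length", "axon_diameter", "axon_length",
             "dend_diameter", "proximal_dend_diameter", "distal_dend_diameter",
             "proximal_dend_length", "distal_dend_length",
             "dend_bend_angle", "dend_bifurcation_angle", "n_dendrites",
             "axon_bend_angle", "axon_terminal_branch_angle",
             "n_axon_terminals", "removed_dendrites")


@dataclass(frozen=True)
class SweepResult:
    parameter: str
    values: tuple
    thresholds: tuple                # signed mV/mm or None
    polarity: str
    fixed_context: ArtificialNeuronParams
    results: tuple                   # ThresholdResult per value

    def to_frame(self) -> pd.DataFrame:
        vals = [repr(sorted(v)) if isinstance(v, (set, frozenset)) else v
                for v in self.values]
        return pd.DataFrame({self.parameter: vals,
                             "E_threshold_mV_per_mm": self.thresholds})


def sweep_threshold(base: ArtificialNeuronParams, parameter: str, values,
                    polarity="+", E_max: float = 1000.0,
                    resolution: float = 0.5,
                    config: SolverConfig = SolverConfig(),
                    biophys: Optional[Biophysics] = None,
                    epsc: Optional[EPSCStimulus] = None) -> SweepResult:
    """Field threshold across a morphology-parameter grid.

    ``biophys`` defaults to the shipped CA1 kinetics file.
    """
    if parameter not in SWEEPABLE:
        raise ParameterError(f"unknown sweep parameter {parameter!r}; "
                             f"one of {SWEEPABLE}")
    if biophys is None:
        biophys = Biophysics.load()
    results = []
    for value in values:
        if parameter == "removed_dendrites":
            params = base.with_(removed_dendrites=frozenset(value))
        else:
            params = base.with_(**{parameter: value})
        tree = build_artificial_neuron(params)
        if epsc is not None and epsc.amplitude > 0:
            res = threshold_with_epsc(tree, biophys, epsc, polarity=polarity,
                                      E_max=E_max, resolution=resolution,
                                      config=config)
        else:
            res = find_EF_threshold(tree, biophys, polarity=polarity,
                                    E_max=E_max, resolution=resolution,
                                    config=config)
        results.append(res)
    return SweepResult(parameter=parameter, values=tuple(values),
                       thresholds=tuple(r.E_threshold for r in results),
                       polarity=_polarity_sign(polarity)[0],
                       fixed_context=base, results=tuple(results))


# ---------------------------------------------------------------------------
# AP-site diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APSiteDiagnostics:
    table: pd.DataFrame              # section, arc, y_um, peak_mV, crossing_ms
    initiation_site: tuple           # (section, arc)

    def peak_at(self, section: str) -> float:
        rows = self.table[self.table.section == section]
        return float(rows.peak_mV.max())


def ap_site_diagnostics(trace: Trace,
                        threshold_mV: float = DETECTION_THRESHOLD_MV,
                        y: Optional[np.ndarray] = None) -> APSiteDiagnostics:
    """Per-site AP peak during the first spike plus the initiation site.

    The trace must record every compartment; the initiation site is the
    earliest upward crossing of the detection threshold (ties broken by the
    highest voltage at the crossing sample).
    """
    t = trace.times
    first_cross = np.full(len(trace.sites), np.inf)
    for i in range(trace.V.shape[0]):
        v = trace.V[i]
        above = v >= threshold_mV
        idx = np.flatnonzero(~above[:-1] & above[1:])
        if idx.size:
            first_cross[i] = t[idx[0] + 1]
    if not np.isfinite(first_cross).any():
        raise ParameterError("no spike in trace; AP diagnostics undefined")
    t0 = first_cross.min()
    window = (t >= t0 - 1.0) & (t <= t0 + 5.0)
    peaks = trace.V[:, window].max(axis=1)
    earliest = np.flatnonzero(first_cross == t0)
    init_i = int(earliest[np.argmax([trace.V[i][t == t0][0] for i in earliest])])
    table = pd.DataFrame({
        "section": [s for s, _ in trace.sites],
        "arc": [a for _, a in trace.sites],
        "peak_mV": peaks,
        "crossing_ms": first_cross,
    })
    if y is not None:
        table["y_um"] = y
    return APSiteDiagnostics(table=table, initiation_site=trace.sites[init_i])


def run_ap_diagnostics(tree: MorphologyTree, biophys: Biophysics, amplitude: float,
                       config: SolverConfig = SolverConfig(),
                       field_onset: float = 100.0,
                       field_offset: float = 600.0) -> APSiteDiagnostics:
    """Simulate at a suprathreshold field recording everywhere, then analyze."""
    system = build_system(tree, biophys, config.max_compartment_length)
    state = init_system_steady_state(system, config)
    cfg = replace(config, record_sites="all", duration=field_offset + 50.0)
    trace = simulate_system(system, [FieldStimulus(amplitude, onset=field_onset,
                                                   offset=field_offset)],
                            cfg, state=state)
    return ap_site_diagnostics(trace, y=system.y.copy())


# ---------------------------------------------------------------------------
# subthreshold polarization summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolarizationFit:
    E: np.ndarray
    soma_delta_v: np.ndarray         # mV
    slope: float                     # mV per (mV/mm)
    intercept: float
    max_residual: float              # mV

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"E_mV_per_mm": self.E,
                             "soma_delta_v_mV": self.soma_delta_v})


def polarization_vs_E(tree: MorphologyTree, biophys: Biophysics, E_grid,
                      config: SolverConfig = SolverConfig()) -> PolarizationFit:
    """Least-squares slope of somatic steady polarization versus field.

    Every grid point must be subthreshold (a spike raises
    SuprathresholdFieldError).
    """
    E_grid = np.asarray(sorted(E_grid), dtype=float)
    system = build_system(tree, biophys, config.max_compartment_length)
    state = init_system_steady_state(system, config)
    dv = np.array([
        steady_state_polarization(tree, biophys, E, config, system=system,
                                  state=state).soma_delta_v if E != 0.0 else 0.0
        for E in E_grid])
    A = np.vstack([E_grid, np.ones_like(E_grid)]).T
    (slope, intercept), *_ = np.linalg.lstsq(A, dv, rcond=None)
    resid = np.abs(dv - (slope * E_grid + intercept)).max()
    return PolarizationFit(E=E_grid, soma_delta_v=dv, slope=float(slope),
                           intercept=float(intercept), max_residual=float(resid))
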