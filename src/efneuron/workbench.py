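"""Configuration, run driver and figure-reproduction battery.

A run is described by a single structured config (YAML on disk, validated
with pydantic before any computation starts). Results are tidy CSV tables
plus a provenance sidecar (resolved config, kinetics-file hash, package
version, seed) so every output is reproducible bit-for-bit from its sidecar.
"""
from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import pydantic
import yaml

from . import __version__
from .biophysics import Biophysics
from .errors import ConfigError
from .field_solver import FieldStimulus, SolverConfig, simulate
from .morphology import ArtificialNeuronParams, build_artificial_neuron
from .protocols import (EPSCStimulus, f_E_curve, find_EF_threshold,
                        polarization_vs_E, sweep_threshold, threshold_with_epsc)
from .swc import read_swc, write_swc
from .synthetic import TreeGenSpec, generate_tree


class MorphologySource(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    kind: Literal["artificial", "swc", "generated"]
    params: dict = {}
    path: Optional[str] = None
    spec: dict = {}


class BiophysicsSettings(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    kinetics_file: Optional[str] = None
    passive_only: bool = False
    e_leak: Optional[float] = None


class SolverSettings(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    dt: float = 0.025
    max_compartment_length: float = 10.0
    steady_state_tolerance: float = 1e-5


class ProtocolSettings(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="allow")
    name: Literal["simulate", "threshold", "sweep", "fe_curve", "polarize",
                  "generate_tree", "reproduce_figures"]


class RunConfig(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    morphology: MorphologySource = MorphologySource(kind="artificial")
    biophysics: BiophysicsSettings = BiophysicsSettings()
    solver: SolverSettings = SolverSettings()
    protocol: ProtocolSettings
    output_dir: str = "efneuron-out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def _validate(config) -> RunConfig:
    if isinstance(config, RunConfig):
        return config
    try:
        return RunConfig.model_validate(config)
    except pydantic.ValidationError as exc:
        keys = ", ".join(".".join(str(p) for p in e["loc"]) for e in exc.errors())
        raise ConfigError(f"invalid run configuration (offending keys: {keys})") from exc


def _resolve_morphology(src: MorphologySource, seed: int):
    if src.kind == "artificial":
        try:
            params = ArtificialNeuronParams(**src.params)
        except TypeError as exc:
            raise ConfigError(f"unknown morphology parameter: {exc}") from exc
        return build_artificial_neuron(params)
    if src.kind == "swc":
        if not src.path:
            raise ConfigError("morphology.path is required for kind 'swc'")
        return read_swc(src.path)
    spec = TreeGenSpec(**{"seed": seed, **src.spec})
    return generate_tree(spec)


def _resolve_biophysics(cfg: BiophysicsSettings) -> Biophysics:
    if cfg.passive_only:
        return Biophysics.passive_only()
    return Biophysics.load(cfg.kinetics_file, e_leak=cfg.e_leak)


class RunResult:
    """Bundle of result tables, status and output paths."""

    def __init__(self, status: str, tables: dict, output_dir: Path, log: list):
        self.status = status
        self.tables = tables
        self.output_dir = output_dir
        self.log = log


def run(config) -> RunResult:
    """Validate, execute the named protocol and write the result bundle."""
    cfg = _validate(config)
    log: list[str] = []

    def note(msg):
        log.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    biophys = _resolve_biophysics(cfg.biophysics)
    tree = _resolve_morphology(cfg.morphology, cfg.seed)
    solver = SolverConfig(dt=cfg.solver.dt,
                          max_compartment_length=cfg.solver.max_compartment_length,
                          steady_state_tolerance=cfg.solver.steady_state_tolerance)
    note(f"efneuron {__version__}; kinetics {biophys.name} "
         f"(sha256 {biophys.source_hash or 'n/a'}); seed {cfg.seed}")
    note(f"morphology: {cfg.morphology.kind} with {len(tree)} sections")

    p = cfg.protocol.model_dump()
    name = p.pop("name")
    status = "ok"
    tables: dict[str, pd.DataFrame] = {}

    if name == "threshold":
        epsc_cfg = p.get("epsc")
        kw = dict(polarity=p.get("polarity", "+"),
                  E_max=p.get("e_max", 1000.0),
                  resolution=p.get("resolution", 0.5), config=solver)
        if epsc_cfg:
            res = threshold_with_epsc(tree, biophys, EPSCStimulus(**epsc_cfg), **kw)
        else:
            res = find_EF_threshold(tree, biophys, **kw)
        tables["threshold"] = pd.DataFrame([{
            "polarity": res.polarity,
            "E_threshold_mV_per_mm": res.E_threshold,
            "resolution_mV_per_mm": res.resolution,
            "bracket_lo": None if res.bracket is None else res.bracket[0],
            "bracket_hi": None if res.bracket is None else res.bracket[1],
            "E_max": res.E_max,
        }])
        if not res.found:
            status = "no-threshold"
        note(f"threshold ({res.polarity}): {res.E_threshold} mV/mm")
    elif name == "sweep":
        res = sweep_threshold(ArtificialNeuronParams(**cfg.morphology.params),
                              p["parameter"], p["values"],
                              polarity=p.get("polarity", "+"),
                              E_max=p.get("e_max", 1000.0),
                              resolution=p.get("resolution", 0.5),
                              config=solver, biophys=biophys)
        tables["sweep"] = res.to_frame()
        if any(t is None for t in res.thresholds):
            status = "no-threshold"
    elif name == "fe_curve":
        curve = f_E_curve(tree, biophys, p["e_grid"], config=solver)
        tables["fe_curve"] = curve.to_frame()
    elif name == "polarize":
        fit = polarization_vs_E(tree, biophys, p["e_grid"], config=solver)
        tables["polarize"] = fit.to_frame()
        tables["polarize_fit"] = pd.DataFrame([{
            "slope_mV_per_mV_per_mm": fit.slope, "intercept_mV": fit.intercept,
            "max_residual_mV": fit.max_residual,
        }])
    elif name == "simulate":
        stim = FieldStimulus(amplitude=p.get("amplitude", 0.0),
                             onset=p.get("onset", 100.0),
                             offset=p.get("offset", 600.0))
        trace = simulate(tree, biophys, [stim] if stim.amplitude else [],
                         SolverConfig(dt=solver.dt,
                                      max_compartment_length=solver.max_compartment_length,
                                      duration=p.get("duration"),
                                      record_sites=tuple(
                                          tuple(s) for s in p.get(
                                              "record_sites", [["soma", 0.5]]))))
        tables["trace"] = trace.to_frame()
    elif name == "generate_tree":
        tables["morphology"] = pd.DataFrame(
            [{"section": s.id, "kind": s.kind, "length_um": s.length,
              "diameter_um": s.diameter} for s in tree])
    elif name == "reproduce_figures":
        outdir = Path(cfg.output_dir)
        tables = reproduce_figures(outdir, biophys=biophys, solver=solver,
                                   seed=cfg.seed,
                                   only=p.get("only"), scale=p.get("scale", "desk"))
    else:  # pragma: no cover - pydantic restricts names
        raise ConfigError(f"unknown protocol {name!r}")

    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tname, frame in tables.items():
        frame.to_csv(outdir / f"{tname}.csv", index=False)
    if cfg.morphology.kind == "generated" or name == "generate_tree":
        write_swc(tree, outdir / "morphology.swc")
    (outdir / "config_resolved.yaml").write_text(
        yaml.safe_dump(cfg.model_dump(), sort_keys=True))
    (outdir / "provenance.json").write_text(json.dumps({
        "package": "efneuron", "version": __version__,
        "kinetics_name": biophys.name, "kinetics_sha256": biophys.source_hash,
        "seed": cfg.seed, "status": status,
    }, indent=2))
    note(f"status: {status}")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return RunResult(status, tables, outdir, log)


# ---------------------------------------------------------------------------
# figure battery
# ---------------------------------------------------------------------------

#: the monotone threshold/morphology relationships of record, with the
#: declared desk-scale grids. Each entry: (name, parameter, grid, expected
#: direction of the positive-polarity threshold, base-parameter overrides).
#: Size grids start at the printed initial value of the default cell and
#: increase from there (the stated baselines are the initial cell).
FIGURE_BATTERY = [
    ("fig2a_soma_diameter", "soma_diameter", [10.0, 15.0, 20.0, 25.0],
     "decreasing", {}),
    ("fig2b_axon_diameter", "axon_diameter", [2.0, 3.0, 4.0, 5.0],
     "increasing", {}),
    ("fig2c_proximal_dend_diameter", "proximal_dend_diameter",
     [1.0, 2.0, 3.0, 4.0], "decreasing", {}),
    ("fig2d_distal_dend_diameter", "distal_dend_diameter",
     [1.0, 2.0, 3.0, 4.0], "decreasing", {}),
    ("fig3a_soma_length", "soma_length", [10.0, 15.0, 20.0, 25.0],
     "decreasing", {}),
    ("fig3b_axon_length", "axon_length", [50.0, 80.0, 120.0, 160.0],
     "decreasing", {}),
    ("fig3c_proximal_dend_length", "proximal_dend_length",
     [8.0, 14.0, 20.0, 26.0], "decreasing", {}),
    ("fig3d_distal_dend_length", "distal_dend_length",
     [2.0, 8.0, 14.0, 20.0], "decreasing", {}),
    ("fig4a_dend_bend", "dend_bend_angle", [0.0, 25.0, 50.0, 75.0],
     "increasing", {"dend_diameter": 2.0, "proximal_dend_length": 8.0,
                    "distal_dend_length": 8.0}),
    ("fig4b_dend_bifurcation", "dend_bifurcation_angle",
     [0.0, 30.0, 60.0, 90.0], "increasing",
     {"dend_diameter": 2.0, "proximal_dend_length": 8.0,
      "distal_dend_length": 8.0}),
    ("fig4c_dendrite_number", "n_dendrites", [6, 9, 12, 15],
     "decreasing", {"dend_diameter": 2.0, "proximal_dend_length": 8.0,
                    "distal_dend_length": 8.0}),
    ("fig5_dendrite_removal", "removed_dendrites",
     [frozenset(), frozenset({"dend11", "dend12"}),
      frozenset({"dend9", "dend10", "dend11", "dend12"}),
      frozenset({"dend5", "dend6", "dend7", "dend8",
                 "dend9", "dend10", "dend11", "dend12"})],
     "increasing", {}),
    ("fig6a_axon_bend", "axon_bend_angle", [0.0, 25.0, 50.0, 75.0],
     "decreasing", {}),
    ("fig6c_terminal_branch_angle", "axon_terminal_branch_angle",
     [10.0, 30.0, 50.0, 70.0], "decreasing",
     {"n_axon_terminals": 2, "axon_terminal_length": 20.0,
      "axon_terminal_diameter": 2.0}),
    ("fig6d_terminal_number", "n_axon_terminals", [1, 2, 3, 4],
     "increasing", {"axon_terminal_branch_angle": 0.0,
                    "axon_terminal_length": 20.0,
                    "axon_terminal_diameter": 2.0}),
]


def monotone_direction(values, resolution: float) -> str:
    """Classify a threshold series as increasing/decreasing/non-monotonic.

    Steps smaller than the search resolution are treated as ties.
    """
    vals = [v for v in values]
    if any(v is None for v in vals):
        return "undefined"
    diffs = np.diff(np.asarray(vals, dtype=float))
    if np.all(diffs <= resolution) and vals[-1] < vals[0] - resolution:
        return "decreasing"
    if np.all(diffs >= -resolution) and vals[-1] > vals[0] + resolution:
        return "increasing"
    return "non-monotonic"


def run_direction_battery(biophys: Optional[Biophysics] = None,
                          solver: SolverConfig = SolverConfig(),
                          resolution: float = 0.5, e_max: float = 1000.0,
                          only=None) -> tuple[dict, pd.DataFrame]:
    """Run the figure sweeps; return per-figure tables and a summary."""
    if biophys is None:
        biophys = Biophysics.load()
    tables, rows = {}, []
    for name, parameter, grid, expected, overrides in FIGURE_BATTERY:
        if only is not None and name not in only:
            continue
        base = ArtificialNeuronParams(**overrides)
        sweep = sweep_threshold(base, parameter, grid, polarity="+",
                                E_max=e_max, resolution=resolution,
                                config=solver, biophys=biophys)
        tables[name] = sweep.to_frame()
        observed = monotone_direction(sweep.thresholds, resolution)
        rows.append({"figure": name, "parameter": parameter,
                     "expected_direction": expected,
                     "observed_direction": observed,
                     "match": observed == expected})
    return tables, pd.DataFrame(rows)


def run_epsp_battery(biophys: Optional[Biophysics] = None,
                     solver: SolverConfig = SolverConfig(),
                     axon_lengths=(30.0, 80.0),
                     amplitudes=(0.0, 0.01, 0.03),
                     resolution: float = 0.5, e_max: float = 1000.0) -> pd.DataFrame:
    """Thresholds with EPSC co-stimulation across axon lengths (Fig 7 style)."""
    if biophys is None:
        biophys = Biophysics.load()
    rows = []
    for L in axon_lengths:
        tree = build_artificial_neuron(ArtificialNeuronParams(axon_length=L))
        for amp in amplitudes:
            if amp == 0.0:
                res = find_EF_threshold(tree, biophys, "+", E_max=e_max,
                                        resolution=resolution, config=solver)
            else:
                res = threshold_with_epsc(
                    tree, biophys, EPSCStimulus(amplitude=amp), "+",
                    E_max=e_max, resolution=resolution, config=solver)
            rows.append({"axon_length_um": L, "epsc_nA": amp,
                         "E_threshold_mV_per_mm": res.E_threshold})
    return pd.DataFrame(rows)


def reproduce_figures(outdir, biophys: Optional[Biophysics] = None,
                      solver: SolverConfig = SolverConfig(), seed: int = 0,
                      only=None, scale: str = "desk") -> dict:
    """Write the per-figure sweep CSVs and the direction summary.

    ``scale='smoke'`` trims every grid to its endpoints (used for quick
    validation runs); the declared desk-scale grids are the defaults.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if biophys is None:
        biophys = Biophysics.load()
    battery = FIGURE_BATTERY
    if scale == "smoke":
        battery = [(n, p, [g[0], g[-1]], e, o) for n, p, g, e, o in battery]
    tables, rows = {}, []
    for name, parameter, grid, expected, overrides in battery:
        if only is not None and name not in only:
            continue
        base = ArtificialNeuronParams(**overrides)
        sweep = sweep_threshold(base, parameter, grid, polarity="+",
                                config=solver, biophys=biophys)
        tables[name] = sweep.to_frame()
        observed = monotone_direction(sweep.thresholds, sweep.results[0].resolution)
        rows.append({"figure": name, "parameter": parameter,
                     "expected_direction": expected,
                     "observed_direction": observed,
                     "match": observed == expected})
    if only is None:
        epsp = run_epsp_battery(biophys, solver)
        tables["fig7_epsp"] = epsp
        ok = all(
            np.all(np.diff(sub.sort_values("epsc_nA").E_threshold_mV_per_mm) < 0)
            for _, sub in epsp.groupby("axon_length_um"))
        rows.append({"figure": "fig7_epsp", "parameter": "epsc_nA",
                     "expected_direction": "decreasing",
                     "observed_direction": "decreasing" if ok else "non-monotonic",
                     "match": bool(ok)})
        # Fig 8c analogue: somatic polarization slope for generated trees
        pol_rows = []
        for label, frac in (("anode_heavy", 0.8), ("balanced", 0.5),
                            ("cathode_heavy", 0.2)):
            tree = generate_tree(TreeGenSpec(anode_side_fraction=frac, seed=seed))
            fit = polarization_vs_E(tree, biophys, [-50.0, -25.0, 0.0, 25.0, 50.0],
                                    config=solver)
            pol_rows.append({"morphology": label, "anode_side_fraction": frac,
                             "slope_mV_per_mV_per_mm": fit.slope,
                             "max_residual_mV": fit.max_residual})
        tables["fig8c_polarization"] = pd.DataFrame(pol_rows)
    summary = pd.DataFrame(rows)
    tables["summary"] = summary
    for name, frame in tables.items():
        frame.to_csv(outdir / f"{name}.csv", index=False)
    return tables
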