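"""Membrane biophysics: passive constants and voltage-gated channels.

The membrane carries a passive leak (conductance 1/Rm) and up to four active
currents -- transient Na+, delayed-rectifier K+, A-type K+ and the
hyperpolarization-activated cation current I_h -- each with a peak
conductance density that may grow linearly with path distance from the soma
on dendritic sections. Kinetics and reversal potentials are loaded from a
versioned YAML parameter file (see ``efneuron/data/ca1_kinetics.yaml``);
nothing electrophysiological is hard-coded here except the unit conventions.

Unit conventions: voltages mV, time ms, conductance densities pS/μm²,
per-area currents μA/cm². The single conversion constant
``PS_PER_UM2_TO_MS_PER_CM2`` (1 pS/μm² = 0.1 mS/cm²) is defined here and
used everywhere.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .errors import ParameterError
from .kinetics import GateSpec
from .morphology import SECTION_KINDS

#: 1 pS/μm² expressed in mS/cm² -- the only density unit conversion in the code
PS_PER_UM2_TO_MS_PER_CM2 = 0.1


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane constants.

    cm: μF/cm²; ra: Ω·cm (cytoplasmic resistivity); rm: kΩ·cm² (membrane
    resistance, leak conductance = 1/rm); e_leak: mV.
    """

    cm: float = 1.0
    ra: float = 80.0
    rm: float = 28.0
    e_leak: float = -65.0

    def __post_init__(self):
        for name in ("cm", "ra", "rm"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")

    @property
    def g_leak_mS_per_cm2(self) -> float:
        return 1.0 / self.rm  # kΩ·cm² -> mS/cm²


@dataclass(frozen=True)
class ChannelDensityRule:
    """Peak conductance density as a function of path distance from soma.

    ``somatic_density`` in pS/μm²; ``slope`` in pS/μm² per 100 μm of path
    distance, applied only on section kinds in ``applies_to`` (the density is
    flat at the somatic value elsewhere).
    """

    channel: str
    somatic_density: float
    slope: float = 0.0
    applies_to: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.somatic_density < 0:
            raise ParameterError(f"{self.channel}: somatic density must be >= 0")
        bad = set(self.applies_to) - set(SECTION_KINDS)
        if bad:
            raise ParameterError(f"{self.channel}: unknown section kinds {sorted(bad)}")
        object.__setattr__(self, "applies_to", frozenset(self.applies_to))


def density_at(rule: ChannelDensityRule, dist: float,
               section_kind: str = "soma") -> float:
    """Evaluate a density rule at a path distance (μm) on a given section kind."""
    if dist < 0:
        raise ParameterError("path distance must be >= 0")
    if section_kind in rule.applies_to:
        return rule.somatic_density + rule.slope * dist / 100.0
    return rule.somatic_density


@dataclass(frozen=True)
class Channel:
    """A voltage-gated channel: density rule + gates + reversal potential."""

    name: str
    reversal: float  # mV
    density: ChannelDensityRule
    gates: tuple[GateSpec, ...]


@dataclass(frozen=True)
class MembraneState:
    """Per-compartment transmembrane voltage and gating variables.

    V = V_in - V_ext (mV). ``gates`` maps "Channel.gate" to an array aligned
    with V.
    """

    V: np.ndarray
    gates: Mapping[str, np.ndarray]


class Biophysics:
    """Bundle of passive constants, channels and provenance metadata."""

    def __init__(self, passive: PassiveParams, channels: Sequence[Channel] = (),
                 temperature_c: float = 24.0, source: Optional[str] = None,
                 source_hash: Optional[str] = None, name: str = "custom",
                 version: object = None):
        self.passive = passive
        self.channels = tuple(channels)
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ParameterError("duplicate channel names")
        self.temperature_c = temperature_c
        self.source = source
        self.source_hash = source_hash
        self.name = name
        self.version = version

    def channel(self, name: str) -> Channel:
        for c in self.channels:
            if c.name == name:
                return c
        raise ParameterError(f"unknown channel {name!r}")

    @property
    def is_passive(self) -> bool:
        return not self.channels

    # -- construction -----------------------------------------------------

    @staticmethod
    def default_kinetics_path() -> Path:
        return Path(resources.files("efneuron").joinpath("data/ca1_kinetics.yaml"))

    @classmethod
    def load(cls, path=None, e_leak: Optional[float] = None) -> "Biophysics":
        """Load from a kinetics parameter file (default: the shipped CA1 set)."""
        path = Path(path) if path is not None else cls.default_kinetics_path()
        raw = path.read_bytes()
        doc = yaml.safe_load(raw)
        pas = doc["passive"]
        passive = PassiveParams(cm=pas["cm_uF_per_cm2"], ra=pas["ra_ohm_cm"],
                                rm=pas["rm_kohm_cm2"],
                                e_leak=pas["e_leak_mV"] if e_leak is None else e_leak)
        rev = doc.get("reversal_potentials_mV", {})
        channels = []
        for cname, cdoc in doc.get("channels", {}).items():
            dens = cdoc["density"]
            rule = ChannelDensityRule(
                channel=cname,
                somatic_density=float(dens["somatic_pS_per_um2"]),
                slope=float(dens.get("slope_pS_per_um2_per_100um", 0.0)),
                applies_to=frozenset(dens.get("slope_applies_to", [])),
            )
            gates = tuple(GateSpec.from_dict(g) for g in cdoc["gates"])
            erev = cdoc["reversal"]
            erev = float(rev[erev]) if isinstance(erev, str) else float(erev)
            channels.append(Channel(cname, erev, rule, gates))
        return cls(passive, channels,
                   temperature_c=float(doc.get("temperature_c", 24.0)),
                   source=str(path),
                   source_hash=hashlib.sha256(raw).hexdigest(),
                   name=doc.get("name", path.stem), version=doc.get("version"))

    @classmethod
    def passive_only(cls, passive: Optional[PassiveParams] = None) -> "Biophysics":
        return cls(passive or PassiveParams(), (), name="passive")

    # -- per-area current -------------------------------------------------

    def membrane_current(self, v, gate_values: Mapping[str, object],
                         densities: Mapping[str, float]) -> np.ndarray:
        """Total ionic current density I_ion in μA/cm².

        ``densities`` gives each channel's local peak density in pS/μm²;
        ``gate_values`` maps "Channel.gate" to values in [0, 1]. Leak is
        always included: (V - E_leak)/Rm.
        """
        v = np.asarray(v, dtype=float)
        i = self.passive.g_leak_mS_per_cm2 * (v - self.passive.e_leak)
        for ch in self.channels:
            g = densities.get(ch.name, 0.0) * PS_PER_UM2_TO_MS_PER_CM2
            open_frac = np.ones_like(v)
            for gate in ch.gates:
                x = np.asarray(gate_values[f"{ch.name}.{gate.name}"], dtype=float)
                open_frac = open_frac * x ** gate.exponent
            i = i + g * open_frac * (v - ch.reversal)
        return i  # mS/cm² * mV = μA/cm²

    # -- kinetics tables for the solver ------------------------------------

    def gate_list(self) -> list[tuple[str, GateSpec]]:
        """Flat (channel_name, gate) list in deterministic order."""
        return [(ch.name, g) for ch in self.channels for g in ch.gates]

    def tabulate_gates(self, vgrid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (inf, tau) tables of shape (n_gates, len(vgrid))."""
        pairs = [g.evaluate(vgrid, self.temperature_c) for _, g in self.gate_list()]
        if not pairs:
            return (np.zeros((0, len(vgrid))), np.ones((0, len(vgrid))))
        inf = np.stack([p[0] for p in pairs])
        tau = np.stack([p[1] for p in pairs])
        return inf, tau


def load_kinetics(path=None, **kw) -> Biophysics:
    """Convenience alias for :meth:`Biophysics.load`."""
    return Biophysics.load(path, **kw)
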