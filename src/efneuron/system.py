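"""Discretization of a morphology into a compartmental cable system.

Each section is cut into an odd number of equal compartments no longer than
the configured maximum, so every section has a true midpoint compartment
(the soma midpoint is the canonical recording site). Membrane dynamics are
evaluated at compartment centers; adjacent centers are coupled by the axial
conductance of the intervening half-compartments.

Internal solver units: mV, ms, μS, nF, nA (so C·dV/dt and g·V are both nA).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .biophysics import Biophysics, PS_PER_UM2_TO_MS_PER_CM2, density_at
from .errors import MorphologyError, ParameterError
from .kinetics import table_grid
from .morphology import MorphologyTree, path_distance_from_soma


def axial_conductance(d1_um: float, dx1_um: float, d2_um: float, dx2_um: float,
                      ra_ohm_cm: float) -> float:
    """Axial conductance (μS) between the centers of two adjacent compartments.

    The series combination of the two half-compartment resistances
    R_i = 4·Ra·Δx_i/(π·d_i²); for a uniform cylinder this reduces to
    (π·d²/4)/(Ra·Δx).
    """
    if min(d1_um, dx1_um, d2_um, dx2_um, ra_ohm_cm) <= 0:
        raise ParameterError("diameters, lengths and Ra must be > 0")
    # full-compartment resistance in MΩ: Ra[Ω·cm]·Δx[μm] / (area[μm²] · 100)
    r1 = ra_ohm_cm * dx1_um / (math.pi * d1_um ** 2 / 4.0) / 100.0
    r2 = ra_ohm_cm * dx2_um / (math.pi * d2_um ** 2 / 4.0) / 100.0
    return 1.0 / (0.5 * r1 + 0.5 * r2)


def compartment_count(length_um: float, max_len_um: float) -> int:
    """Smallest odd compartment count with Δx <= max_len."""
    n = max(1, math.ceil(length_um / max_len_um - 1e-12))
    return n if n % 2 == 1 else n + 1


@dataclass
class CompartmentalSystem:
    """Flattened arrays describing the discretized neuron.

    Compartments are topologically ordered (every parent index is smaller
    than its children), which is what the direct tree solve requires.
    """

    tree: MorphologyTree
    biophys: Biophysics
    max_compartment_length: float

    # per-compartment geometry
    section_id: list            # section id per compartment
    sec_kind: list
    arc: np.ndarray             # center arc position within the section
    x: np.ndarray               # μm
    y: np.ndarray
    dx: np.ndarray
    diam: np.ndarray
    area: np.ndarray            # μm² (lateral)
    path_dist: np.ndarray       # μm from soma midpoint

    parent: np.ndarray          # int64, -1 for root compartment
    g_ax: np.ndarray            # μS to parent
    C: np.ndarray               # nF
    g_leak: np.ndarray          # μS
    e_leak: float

    chan_g: np.ndarray          # (nchan, ncomp) μS at full open
    chan_E: np.ndarray          # (nchan,)
    gate_chan: np.ndarray       # (ngate,) channel index per gate
    gate_exp: np.ndarray        # (ngate,)
    gate_names: list            # "Channel.gate"
    inf_tab: np.ndarray         # (ngate, nV)
    tau_tab: np.ndarray

    _sec_comps: dict = None     # section id -> (first, count)

    @property
    def n(self) -> int:
        return self.parent.shape[0]

    # -- site resolution --------------------------------------------------

    def compartments_of(self, section: str) -> range:
        first, count = self._sec_comps[section]
        return range(first, first + count)

    def comp_index(self, section: str, arc: float) -> int:
        """Compartment whose center is nearest the requested arc position."""
        if section not in self._sec_comps:
            raise MorphologyError(f"unknown section {section!r}")
        first, count = self._sec_comps[section]
        k = min(count - 1, max(0, int(arc * count)))
        return first + k

    def all_sites(self) -> list:
        return [(self.section_id[i], float(self.arc[i])) for i in range(self.n)]

    def axial_conductance_between(self, i: int, j: int) -> float:
        """Conductance between two adjacent compartments (μS)."""
        if self.parent[j] == i:
            return float(self.g_ax[j])
        if self.parent[i] == j:
            return float(self.g_ax[i])
        raise ParameterError(f"compartments {i} and {j} are not adjacent")

    def resting_gates(self, v: np.ndarray) -> np.ndarray:
        """Gate values at their voltage-dependent steady state (ngate, n)."""
        ngate = self.gate_chan.shape[0]
        gates = np.empty((ngate, self.n))
        grid = table_grid()
        for g in range(ngate):
            gates[g] = np.interp(v, grid, self.inf_tab[g])
        return gates

    def laplacian_apply(self, values: np.ndarray) -> np.ndarray:
        """Σ_k g_ik (u_k - u_i) for every compartment i (units μS·[u])."""
        out = np.zeros(self.n)
        for i in range(1, self.n):
            p = self.parent[i]
            e = self.g_ax[i] * (values[p] - values[i])
            out[i] += e
            out[p] -= e
        return out


def build_system(tree: MorphologyTree, biophys: Biophysics,
                 max_compartment_length: float = 10.0) -> CompartmentalSystem:
    """Discretize a validated tree under the given biophysics."""
    tree.validate()
    if max_compartment_length <= 0:
        raise ParameterError("max_compartment_length must be > 0")
    pas = biophys.passive

    section_id, sec_kind = [], []
    arc_l, x_l, y_l, dx_l, dd_l, pd_l = [], [], [], [], [], []
    parent_l, gax_l = [], []
    sec_comps: dict[str, tuple[int, int]] = {}

    order = tree.topological_order()
    for sec in order:
        ncomp = compartment_count(sec.length, max_compartment_length)
        delta = sec.length / ncomp
        first = len(parent_l)
        sec_comps[sec.id] = (first, ncomp)
        for k in range(ncomp):
            a = (k + 0.5) / ncomp
            pt = sec.point_at(a)
            section_id.append(sec.id)
            sec_kind.append(sec.kind)
            arc_l.append(a)
            x_l.append(pt.x)
            y_l.append(pt.y)
            dx_l.append(delta)
            dd_l.append(sec.diameter)
            pd_l.append(path_distance_from_soma(tree, sec.id, a))
            if k > 0:
                parent_l.append(first + k - 1)
                gax_l.append(axial_conductance(sec.diameter, delta,
                                               sec.diameter, delta, pas.ra))
            elif sec.parent is None:
                parent_l.append(-1)
                gax_l.append(0.0)
            else:
                pfirst, pcount = sec_comps[sec.parent]
                pidx = pfirst if sec.attach_end == "proximal" else pfirst + pcount - 1
                psec = tree.section(sec.parent)
                pdelta = psec.length / pcount
                parent_l.append(pidx)
                gax_l.append(axial_conductance(sec.diameter, delta,
                                               psec.diameter, pdelta, pas.ra))

    area = np.pi * np.asarray(dd_l) * np.asarray(dx_l)
    C = pas.cm * area * 1e-5                          # μF/cm² · μm² -> nF
    g_leak = pas.g_leak_mS_per_cm2 * area * 1e-5      # mS/cm² · μm² -> μS

    nchan = len(biophys.channels)
    n = len(parent_l)
    chan_g = np.zeros((nchan, n))
    chan_E = np.zeros(nchan)
    for c, ch in enumerate(biophys.channels):
        chan_E[c] = ch.reversal
        for i in range(n):
            dens = density_at(ch.density, pd_l[i], sec_kind[i])
            chan_g[c, i] = dens * PS_PER_UM2_TO_MS_PER_CM2 * 1e-5 * area[i]  # pS/μm² -> μS

    gl = biophys.gate_list()
    gate_chan = np.array([next(c for c, ch in enumerate(biophys.channels)
                               if ch.name == cname) for cname, _ in gl],
                         dtype=np.int64)
    gate_exp = np.array([g.exponent for _, g in gl], dtype=np.int64)
    gate_names = [f"{cname}.{g.name}" for cname, g in gl]
    inf_tab, tau_tab = biophys.tabulate_gates(table_grid())

    return CompartmentalSystem(
        tree=tree, biophys=biophys, max_compartment_length=max_compartment_length,
        section_id=section_id, sec_kind=sec_kind,
        arc=np.asarray(arc_l), x=np.asarray(x_l), y=np.asarray(y_l),
        dx=np.asarray(dx_l), diam=np.asarray(dd_l), area=area,
        path_dist=np.asarray(pd_l),
        parent=np.asarray(parent_l, dtype=np.int64), g_ax=np.asarray(gax_l),
        C=C, g_leak=g_leak, e_leak=pas.e_leak,
        chan_g=chan_g, chan_E=chan_E, gate_chan=gate_chan, gate_exp=gate_exp,
        gate_names=gate_names, inf_tab=inf_tab, tau_tab=tau_tab,
        _sec_comps=sec_comps)
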