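"""Branched neuron geometry.

A morphology is a rooted tree of cylindrical sections embedded in the plane.
The vertical (y) axis is the somato-dendritic axis: dendrites extend toward
+y, the axon toward -y, and an applied uniform field is (by convention)
parallel to y. All lengths are in micrometres and all angles in degrees.

The module provides the parametric "artificial neuron" builder -- a soma, an
axon (optionally bent, with terminal branches) and a fan of proximal
dendrites each carrying distal daughters -- together with the morphological
edits used in parameter sweeps (bends, branch-angle changes, dendrite
removal) and SWC import/export (see :mod:`efneuron.swc`).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional

from .errors import MorphologyError, ParameterError

SECTION_KINDS = ("soma", "axon", "axon_terminal", "dend_proximal", "dend_distal")
DENDRITIC_KINDS = frozenset({"dend_proximal", "dend_distal"})
AXONAL_KINDS = frozenset({"axon", "axon_terminal"})

#: geometric coincidence tolerance for attachment points, in μm
ATTACH_TOL = 1e-6

#: angular spacing of the proximal-dendrite fan about the +y axis, degrees
FAN_SPACING_DEG = 10.0


@dataclass(frozen=True)
class Point2D:
    """A planar point; y is the somato-dendritic / field axis (μm)."""

    x: float
    y: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ParameterError("Point2D coordinates must be finite")

    def distance(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)

    def translated(self, dx: float, dy: float) -> "Point2D":
        return Point2D(self.x + dx, self.y + dy)


@dataclass(frozen=True)
class SectionSpec:
    """One cylindrical section of the tree.

    ``parent`` is the id of the parent section (``None`` only for the soma)
    and ``attach_end`` names the parent's end the section attaches to; the
    section's own proximal point must coincide with that attachment point.
    """

    id: str
    kind: str
    proximal: Point2D
    distal: Point2D
    diameter: float
    parent: Optional[str] = None
    attach_end: str = "distal"

    def __post_init__(self):
        if self.kind not in SECTION_KINDS:
            raise ParameterError(f"unknown section kind {self.kind!r}")
        if self.attach_end not in ("proximal", "distal"):
            raise ParameterError(f"attach_end must be proximal|distal, got {self.attach_end!r}")
        if not self.diameter > 0:
            raise ParameterError(f"section {self.id!r}: diameter must be > 0")
        if not self.length > 0:
            raise ParameterError(f"section {self.id!r}: zero-length section")

    @property
    def length(self) -> float:
        return self.proximal.distance(self.distal)

    @property
    def center(self) -> Point2D:
        return Point2D(0.5 * (self.proximal.x + self.distal.x),
                       0.5 * (self.proximal.y + self.distal.y))

    def end(self, which: str) -> Point2D:
        return self.proximal if which == "proximal" else self.distal

    def point_at(self, arc: float) -> Point2D:
        """Point at fractional arc position (0 = proximal, 1 = distal)."""
        return Point2D(self.proximal.x + arc * (self.distal.x - self.proximal.x),
                       self.proximal.y + arc * (self.distal.y - self.proximal.y))


class MorphologyTree:
    """Rooted tree of sections with free-form metadata labels."""

    def __init__(self, sections: Iterable[SectionSpec],
                 metadata: Optional[Mapping] = None):
        self._sections: dict[str, SectionSpec] = {}
        for sec in sections:
            if sec.id in self._sections:
                raise MorphologyError(f"duplicate section id {sec.id!r}")
            self._sections[sec.id] = sec
        self.metadata: dict = dict(metadata or {})
        self._children: dict[str, list[str]] = {sid: [] for sid in self._sections}
        for sec in self._sections.values():
            if sec.parent is not None:
                if sec.parent not in self._sections:
                    raise MorphologyError(
                        f"section {sec.id!r} references missing parent {sec.parent!r}")
                self._children[sec.parent].append(sec.id)

    # -- accessors --------------------------------------------------------

    def __len__(self) -> int:
        return len(self._sections)

    def __iter__(self) -> Iterator[SectionSpec]:
        return iter(self._sections.values())

    def __contains__(self, sid: str) -> bool:
        return sid in self._sections

    @property
    def sections(self) -> list[SectionSpec]:
        return list(self._sections.values())

    def section(self, sid: str) -> SectionSpec:
        try:
            return self._sections[sid]
        except KeyError:
            raise MorphologyError(f"unknown section {sid!r}") from None

    def children(self, sid: str) -> list[SectionSpec]:
        self.section(sid)
        return [self._sections[c] for c in self._children[sid]]

    @property
    def root(self) -> SectionSpec:
        roots = [s for s in self._sections.values() if s.parent is None]
        if len(roots) != 1:
            raise MorphologyError(f"tree must have exactly one root, found {len(roots)}")
        return roots[0]

    def topological_order(self) -> list[SectionSpec]:
        """Sections ordered so every parent precedes its children."""
        order: list[SectionSpec] = []
        stack = [self.root.id]
        while stack:
            sid = stack.pop(0)
            order.append(self._sections[sid])
            stack.extend(self._children[sid])
        if len(order) != len(self._sections):
            raise MorphologyError("tree is not connected")
        return order

    def soma_center(self) -> Point2D:
        return self.root.center

    def dendritic_sections(self) -> list[SectionSpec]:
        return [s for s in self._sections.values() if s.kind in DENDRITIC_KINDS]

    def total_dendritic_length(self) -> float:
        return sum(s.length for s in self.dendritic_sections())

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) over all section endpoints."""
        xs = [p.x for s in self for p in (s.proximal, s.distal)]
        ys = [p.y for s in self for p in (s.proximal, s.distal)]
        return min(xs), max(xs), min(ys), max(ys)

    def attachment_point(self, sec: SectionSpec) -> Point2D:
        """Point on the parent where ``sec`` attaches."""
        if sec.parent is None:
            raise MorphologyError(f"root section {sec.id!r} has no attachment")
        return self.section(sec.parent).end(sec.attach_end)

    # -- validation -------------------------------------------------------

    def validate(self) -> "MorphologyTree":
        """Check every structural invariant; return self for chaining."""
        root = self.root
        if root.kind != "soma":
            raise MorphologyError("root section must be the soma")
        order = self.topological_order()  # also checks connectivity/acyclicity
        for sec in order:
            if sec.parent is not None:
                attach = self.attachment_point(sec)
                if sec.proximal.distance(attach) > ATTACH_TOL:
                    raise MorphologyError(
                        f"section {sec.id!r}: proximal point does not coincide "
                        f"with parent attachment point")
        return self

    def replaced(self, *sections: SectionSpec) -> "MorphologyTree":
        """Copy of the tree with the given sections substituted by id."""
        new = dict(self._sections)
        for sec in sections:
            if sec.id not in new:
                raise MorphologyError(f"unknown section {sec.id!r}")
            new[sec.id] = sec
        return MorphologyTree(new.values(), self.metadata)


# ---------------------------------------------------------------------------
# artificial neuron
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtificialNeuronParams:
    """Parameters of the artificial CA1-like neuron.

    Lengths/diameters in μm, angles in degrees. Defaults give the reference
    cell: a 10x10 μm soma at the origin, a 50 μm axon toward -y and twelve
    dendrites toward +y (4 proximal of 8 μm carrying 8 distal of 2 μm).
    ``proximal_dend_diameter``/``distal_dend_diameter`` override
    ``dend_diameter`` for one group only, which is how the per-group diameter
    sweeps are expressed.
    """

    soma_length: float = 10.0
    soma_diameter: float = 10.0
    axon_length: float = 50.0
    axon_diameter: float = 2.0
    proximal_dend_length: float = 8.0
    distal_dend_length: float = 2.0
    dend_diameter: float = 1.0
    proximal_dend_diameter: Optional[float] = None
    distal_dend_diameter: Optional[float] = None
    n_dendrites: int = 12
    dend_bend_angle: float = 0.0
    dend_bifurcation_angle: float = 0.0
    axon_bend_angle: float = 0.0
    axon_terminal_branch_angle: float = 0.0
    n_axon_terminals: int = 1
    axon_terminal_length: float = 20.0
    axon_terminal_diameter: float = 2.0
    removed_dendrites: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        positive = ("soma_length", "soma_diameter", "axon_length", "axon_diameter",
                    "proximal_dend_length", "distal_dend_length", "dend_diameter",
                    "axon_terminal_length", "axon_terminal_diameter")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("proximal_dend_diameter", "distal_dend_diameter"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("dend_bend_angle", "dend_bifurcation_angle",
                     "axon_bend_angle", "axon_terminal_branch_angle"):
            v = getattr(self, name)
            if not (0.0 <= v <= 90.0):
                raise ParameterError(f"{name} must lie in [0, 90] degrees")
        for name in ("n_dendrites", "n_axon_terminals"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 0):
                raise ParameterError(f"{name} must be a non-negative integer")
        object.__setattr__(self, "removed_dendrites",
                           frozenset(_canon_dend_id(d) for d in self.removed_dendrites))

    def with_(self, **kw) -> "ArtificialNeuronParams":
        return replace(self, **kw)


def _canon_dend_id(d) -> str:
    if isinstance(d, int):
        return f"dend{d}"
    return str(d)


def n_proximal_dendrites(n_dendrites: int) -> int:
    """Proximal count for a total dendrite count (1 proximal : 2 distal)."""
    if n_dendrites == 0:
        return 0
    return min(n_dendrites, max(1, round(n_dendrites / 3)))


def _unit_from_plus_y(angle_deg: float) -> tuple[float, float]:
    a = math.radians(angle_deg)
    return math.sin(a), math.cos(a)


def _unit_from_minus_y(angle_deg: float) -> tuple[float, float]:
    a = math.radians(angle_deg)
    return math.sin(a), -math.cos(a)


def build_artificial_neuron(params: ArtificialNeuronParams) -> MorphologyTree:
    """Construct the artificial neuron for the given parameters.

    Layout conventions (deterministic; the numbering is part of the contract):

    * the soma spans (0, -L/2)..(0, +L/2) so its midpoint is the origin;
    * the axon leaves the soma's proximal (-y) end, tilted ``axon_bend_angle``
      from the -y axis toward +x;
    * proximal dendrites dend1..dendP fan from the soma's distal (+y) end at
      10° spacing symmetric about +y, each tilted a further
      ``dend_bend_angle`` away from vertical (carrying its daughters rigidly);
    * distal dendrites dendP+1..dendN attach in contiguous blocks to the
      proximal dendrites in order (for the default cell dend5/dend6 belong to
      dend1, ... dend11/dend12 to dend4) and split symmetrically by
      ``dend_bifurcation_angle`` (±α/2 about the parent axis);
    * axon terminal branches term1..termK (each
      ``axon_terminal_length`` x ``axon_terminal_diameter``) are appended at
      the axon tip only when ``n_axon_terminals >= 2`` or the terminal branch
      angle is nonzero -- with one straight terminal the axon tip itself is
      the terminal, which keeps the default cell at 14 sections.
    """
    p = params  # validated in __post_init__
    sections: list[SectionSpec] = []
    half = p.soma_length / 2.0
    soma = SectionSpec("soma", "soma", Point2D(0.0, -half), Point2D(0.0, half),
                       p.soma_diameter, parent=None)
    sections.append(soma)

    # axon
    ux, uy = _unit_from_minus_y(p.axon_bend_angle)
    ax_prox = soma.proximal
    ax_dist = Point2D(ax_prox.x + p.axon_length * ux, ax_prox.y + p.axon_length * uy)
    sections.append(SectionSpec("axon", "axon", ax_prox, ax_dist, p.axon_diameter,
                                parent="soma", attach_end="proximal"))

    # axon terminal branches
    if p.n_axon_terminals >= 1 and (p.n_axon_terminals >= 2
                                    or p.axon_terminal_branch_angle > 0):
        k = p.n_axon_terminals
        if k == 1:
            offsets = [p.axon_terminal_branch_angle]
        else:
            a = p.axon_terminal_branch_angle
            offsets = [(-a + 2 * a * i / (k - 1)) for i in range(k)]
        for i, off in enumerate(offsets, start=1):
            tx, ty = _unit_from_minus_y(p.axon_bend_angle + off)
            dist = Point2D(ax_dist.x + p.axon_terminal_length * tx,
                           ax_dist.y + p.axon_terminal_length * ty)
            sections.append(SectionSpec(f"term{i}", "axon_terminal", ax_dist, dist,
                                        p.axon_terminal_diameter,
                                        parent="axon", attach_end="distal"))

    # dendrites
    n_prox = n_proximal_dendrites(p.n_dendrites)
    n_dist = p.n_dendrites - n_prox
    prox_diam = p.proximal_dend_diameter if p.proximal_dend_diameter is not None else p.dend_diameter
    dist_diam = p.distal_dend_diameter if p.distal_dend_diameter is not None else p.dend_diameter

    prox_angle: dict[int, float] = {}
    for i in range(1, n_prox + 1):
        offset = (i - (n_prox + 1) / 2.0) * FAN_SPACING_DEG
        sgn = 1.0 if offset >= 0 else -1.0
        angle = offset + sgn * p.dend_bend_angle
        prox_angle[i] = angle
        ux, uy = _unit_from_plus_y(angle)
        prox = soma.distal
        dist = Point2D(prox.x + p.proximal_dend_length * ux,
                       prox.y + p.proximal_dend_length * uy)
        sections.append(SectionSpec(f"dend{i}", "dend_proximal", prox, dist,
                                    prox_diam, parent="soma", attach_end="distal"))

    # contiguous block assignment of distal dendrites to proximal parents
    counts = [n_dist // n_prox + (1 if i < n_dist % n_prox else 0)
              for i in range(n_prox)] if n_prox else []
    num = n_prox + 1
    for pi, count in enumerate(counts, start=1):
        parent_sec = next(s for s in sections if s.id == f"dend{pi}")
        if count == 1:
            rels = [0.0]
        elif count > 1:
            a = p.dend_bifurcation_angle
            rels = [a / 2.0 - a * j / (count - 1) for j in range(count)]
        else:
            rels = []
        for rel in rels:
            ux, uy = _unit_from_plus_y(prox_angle[pi] + rel)
            prox = parent_sec.distal
            dist = Point2D(prox.x + p.distal_dend_length * ux,
                           prox.y + p.distal_dend_length * uy)
            sections.append(SectionSpec(f"dend{num}", "dend_distal", prox, dist,
                                        dist_diam, parent=parent_sec.id,
                                        attach_end="distal"))
            num += 1

    tree = MorphologyTree(sections, metadata={
        "proximal_dendrites": [f"dend{i}" for i in range(1, n_prox + 1)],
        "distal_dendrites": [f"dend{i}" for i in range(n_prox + 1, p.n_dendrites + 1)],
        "dendrite_numbers": {f"dend{i}": i for i in range(1, p.n_dendrites + 1)},
    })

    if p.removed_dendrites:
        tree = remove_dendrites(tree, p.removed_dendrites)
    return tree.validate()


def remove_dendrites(tree: MorphologyTree, ids: Iterable) -> MorphologyTree:
    """Remove the named dendrite sections together with their subtrees."""
    targets = {_canon_dend_id(d) for d in ids}
    for t in targets:
        sec = tree.section(t)
        if sec.kind not in DENDRITIC_KINDS:
            raise MorphologyError(f"section {t!r} is not a dendrite")
    doomed: set[str] = set()
    stack = list(targets)
    while stack:
        sid = stack.pop()
        if sid in doomed:
            continue
        doomed.add(sid)
        stack.extend(c.id for c in tree.children(sid))
    kept = [s for s in tree.sections if s.id not in doomed]
    meta = dict(tree.metadata)
    for key in ("proximal_dendrites", "distal_dendrites"):
        if key in meta:
            meta[key] = [d for d in meta[key] if d not in doomed]
    if "dendrite_numbers" in meta:
        meta["dendrite_numbers"] = {k: v for k, v in meta["dendrite_numbers"].items()
                                    if k not in doomed}
    return MorphologyTree(kept, meta)


# ---------------------------------------------------------------------------
# edits
# ---------------------------------------------------------------------------

def _rotate(point: Point2D, about: Point2D, angle_deg: float) -> Point2D:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    dx, dy = point.x - about.x, point.y - about.y
    return Point2D(about.x + c * dx - s * dy, about.y + s * dx + c * dy)


def apply_bend(tree: MorphologyTree, section: str, angle: float) -> MorphologyTree:
    """Rotate a section about its proximal point, away from the y axis.

    The rotation sense is chosen so the section's |x-extent| grows (ties
    break toward +x); descendants are rigidly translated so connectivity and
    all lengths are preserved. Returns a new tree.
    """
    if not (0.0 <= angle <= 90.0):
        raise ParameterError("bend angle must lie in [0, 90] degrees")
    sec = tree.section(section)
    if angle == 0.0:
        return tree
    cand = [_rotate(sec.distal, sec.proximal, sgn * angle) for sgn in (+1.0, -1.0)]
    dx_old = abs(sec.distal.x - sec.proximal.x)
    best = max(cand, key=lambda pt: (abs(pt.x - sec.proximal.x) - dx_old, pt.x))
    new_sec = replace(sec, distal=best)

    shift_x = new_sec.distal.x - sec.distal.x
    shift_y = new_sec.distal.y - sec.distal.y
    updates = [new_sec]
    # translate every descendant attached (directly or transitively) through
    # the moved distal end
    stack = [c.id for c in tree.children(sec.id) if c.attach_end == "distal"]
    while stack:
        sid = stack.pop()
        child = tree.section(sid)
        updates.append(replace(child,
                               proximal=child.proximal.translated(shift_x, shift_y),
                               distal=child.distal.translated(shift_x, shift_y)))
        stack.extend(c.id for c in tree.children(sid))
    return tree.replaced(*updates)


def path_distance_from_soma(tree: MorphologyTree, section: str,
                            arc_position: float = 1.0) -> float:
    """Arc length from the soma midpoint (the recording point) to a point.

    The point is at fractional position ``arc_position`` along ``section``
    (0 = proximal end). The soma's own half-length contributes to the
    distance of everything attached to it.
    """
    if not (0.0 <= arc_position <= 1.0):
        raise ParameterError("arc_position must lie in [0, 1]")
    sec = tree.section(section)
    if sec.parent is None:
        return abs(arc_position - 0.5) * sec.length
    dist = arc_position * sec.length
    node = sec
    while True:
        parent = tree.section(node.parent)
        if parent.parent is None:  # soma: midpoint to either end is L/2
            dist += parent.length / 2.0
            return dist
        dist += parent.length if node.attach_end == "distal" else 0.0
        node = parent
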