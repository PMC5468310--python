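"""SWC import/export for morphology trees.

Standard 7-column SWC (index, type, x, y, z, radius, parent; '#' comments).
Type codes 1 = soma, 2 = axon, 3+ = dendrite. Each parent link becomes one
cylindrical section (sample coordinates are the section's distal point, the
parent sample's the proximal point). The z column is read and written but the
embedding is planar: z is ignored by every downstream computation.

Soma convention: on write the soma cylinder is emitted as two type-1 samples
(proximal, then distal). On read, a type-1 child of the root closes the soma
cylinder; a file whose root has no type-1 child gets a synthetic soma
cylinder of length 2r centred on the root sample and oriented along y.
"""
from __future__ import annotations

import io

from .errors import SWCParseError
from .morphology import MorphologyTree, Point2D, SectionSpec


def _open(stream, mode):
    if isinstance(stream, (str, bytes)) or hasattr(stream, "__fspath__"):
        return open(stream, mode), True
    return stream, False


def read_swc(stream) -> MorphologyTree:
    """Parse SWC from a path or text stream into a MorphologyTree."""
    fh, owned = _open(stream, "r")
    try:
        samples: dict[int, tuple] = {}  # idx -> (type, x, y, z, r, parent)
        order: list[int] = []
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(f"expected 7 columns, got {len(parts)}", lineno)
            try:
                idx = int(parts[0])
                typ = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"non-numeric field ({exc})", lineno) from None
            if idx in samples:
                raise SWCParseError(f"duplicate sample index {idx}", lineno)
            if parent != -1 and parent not in samples:
                raise SWCParseError(
                    f"sample {idx} references missing parent {parent}", lineno)
            if r <= 0:
                raise SWCParseError(f"sample {idx}: non-positive radius", lineno)
            samples[idx] = (typ, x, y, z, r, parent)
            order.append(idx)
    finally:
        if owned:
            fh.close()

    roots = [i for i in order if samples[i][5] == -1]
    if len(roots) != 1:
        raise SWCParseError(f"expected exactly one root sample, found {len(roots)}")
    root = roots[0]
    rtyp, rx, ry, rz, rr, _ = samples[root]
    if rtyp != 1:
        raise SWCParseError(f"root sample {root} is not of soma type (1)")

    children: dict[int, list[int]] = {i: [] for i in order}
    for i in order:
        par = samples[i][5]
        if par != -1:
            children[par].append(i)

    soma_child = next((c for c in children[root] if samples[c][0] == 1), None)
    sections: list[SectionSpec] = []
    # sample index -> (section id owning that point, which end it is)
    anchor: dict[int, tuple[str | None, str]] = {}
    if soma_child is not None:
        styp, sx, sy, sz, sr, _ = samples[soma_child]
        soma = SectionSpec("soma", "soma", Point2D(rx, ry), Point2D(sx, sy),
                           2.0 * rr, parent=None)
        anchor[root] = ("soma", "proximal")
        anchor[soma_child] = ("soma", "distal")
    else:
        soma = SectionSpec("soma", "soma", Point2D(rx, ry - rr), Point2D(rx, ry + rr),
                           2.0 * rr, parent=None)
        anchor[root] = ("soma", "synthetic")
    sections.append(soma)

    sec_of_sample: dict[int, str] = {}
    counter = 0
    for i in order:
        typ, x, y, z, r, parent = samples[i]
        if i == root or i == soma_child:
            continue
        if parent in anchor:
            parent_sec, end = anchor[parent]
            if end == "synthetic":
                # attach to the nearer end of the synthesized soma cylinder
                end = "proximal" if y < ry else "distal"
            prox = sections[0].end(end) if parent_sec == "soma" else None
            if parent_sec != "soma":
                psec = next(s for s in sections if s.id == parent_sec)
                prox = psec.end(end)
        else:
            parent_sec = sec_of_sample[parent]
            psec = next(s for s in sections if s.id == parent_sec)
            end = "distal"
            prox = psec.distal
        counter += 1
        if typ == 1:
            kind, base = "soma", "soma_ext"
        elif typ == 2:
            kind, base = "axon", "axon"
        else:
            parent_kind = next(s for s in sections if s.id == parent_sec).kind
            kind = "dend_proximal" if parent_kind == "soma" else "dend_distal"
            base = "dend"
        sid = f"{base}{counter}"
        sections.append(SectionSpec(sid, kind, prox, Point2D(x, y), 2.0 * r,
                                    parent=parent_sec, attach_end=end))
        sec_of_sample[i] = sid
        anchor[i] = (sid, "distal")

    return MorphologyTree(sections).validate()


def write_swc(tree: MorphologyTree, stream) -> None:
    """Serialize a tree to SWC (two type-1 samples for the soma cylinder)."""
    tree.validate()
    fh, owned = _open(stream, "w")
    try:
        fh.write("# SWC export (index type x y z radius parent)\n")
        root = tree.root
        idx = 1
        lines = []
        # soma: proximal then distal sample
        r = root.diameter / 2.0
        lines.append((1, 1, root.proximal.x, root.proximal.y, 0.0, r, -1))
        lines.append((2, 1, root.distal.x, root.distal.y, 0.0, r, 1))
        sample_of_end = {("soma", "proximal"): 1, ("soma", "distal"): 2}
        idx = 2
        typemap = {"axon": 2, "axon_terminal": 2, "dend_proximal": 3,
                   "dend_distal": 3, "soma": 1}
        for sec in tree.topological_order():
            if sec.parent is None:
                continue
            parent_sample = sample_of_end[(sec.parent, sec.attach_end)]
            idx += 1
            lines.append((idx, typemap[sec.kind], sec.distal.x, sec.distal.y, 0.0,
                          sec.diameter / 2.0, parent_sample))
            sample_of_end[(sec.id, "distal")] = idx
            sample_of_end[(sec.id, "proximal")] = parent_sample
        for (i, t, x, y, z, rad, par) in lines:
            fh.write(f"{i} {t} {x:.4f} {y:.4f} {z:.4f} {rad:.4f} {par}\n")
    finally:
        if owned:
            fh.close()


def swc_string(tree: MorphologyTree) -> str:
    buf = io.StringIO()
    write_swc(tree, buf)
    return buf.getvalue()
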