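"""Planar diagrams of sealed tile complexes.

Every crossing of a tile complex lies inside a tile, so a sealed complex has
an explicit planar diagram obtained by instantiating one crossing template
per tile occurrence and joining corner endpoints with crossing-free arcs
(closure, the three cross connectors, series connectors, insertion splices
and finally the sealing arc).

A crossing is a 4-valent vertex with ports listed in counterclockwise
planar order; ports 0 and 2 carry one strand, ports 1 and 3 the other, and
a flag records which strand passes over.  Arcs pair ports.  The rotation
system makes the diagram checkable: a genuinely planar diagram satisfies
Euler's formula V - E + F = 2, which guards against mis-transcribed
templates or impossible connector routings.

The oriented traversal of a sealed diagram yields the PD code (per
crossing, the four incident arc labels counterclockwise from the incoming
under-strand), crossing signs, the writhe and a signed Gauss code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .expressions import (
    Closure,
    Cross,
    Expression,
    Leaf1,
    Parallel,
    Series,
    validate_expression,
)

__all__ = [
    "OpenDiagram",
    "Diagram",
    "PDCrossing",
    "TraversalError",
    "build_sealed_diagram",
    "close_and_orient",
    "orient_closed",
    "writhe",
]

Plug = tuple  # ("x", crossing_id, port) | ("end", name)


@dataclass
class OpenDiagram:
    """A tangle/complex diagram under construction.

    ``over_02`` has one flag per crossing: True when the strand through
    ports 0 and 2 is the over-strand.  ``links`` pairs plugs (crossing
    ports and named free ends) symmetrically.  ``labels`` optionally tags
    each crossing with the letter of the tile occurrence it came from.
    """

    over_02: list[bool] = field(default_factory=list)
    links: dict[Plug, Plug] = field(default_factory=dict)
    labels: list[Optional[str]] = field(default_factory=list)

    @property
    def n_crossings(self) -> int:
        return len(self.over_02)

    def add_crossing(self, over_02: bool, label: Optional[str] = None) -> int:
        self.over_02.append(over_02)
        self.labels.append(label)
        return len(self.over_02) - 1

    def connect(self, a: Plug, b: Plug) -> None:
        for p in (a, b):
            if p in self.links:
                raise ValueError(f"plug {p!r} already connected")
        self.links[a] = b
        self.links[b] = a

    def disconnect(self, a: Plug, b: Plug) -> None:
        if self.links.get(a) != b:
            raise ValueError(f"plugs {a!r} and {b!r} are not connected")
        del self.links[a]
        del self.links[b]

    def ends(self) -> set[str]:
        return {p[1] for p in self.links if p[0] == "end"}

    def rename_end(self, old: str, new: str) -> None:
        plug_old = ("end", old)
        partner = self.links.pop(plug_old)
        self.links[("end", new)] = partner
        self.links[partner] = ("end", new)

    def partner_of_end(self, name: str) -> Plug:
        return self.links[("end", name)]

    def weld(self, end_a: str, end_b: str) -> tuple[Plug, Plug]:
        """Join two free ends with a crossing-free arc; returns the plug
        pair that now forms the arc (oriented a-side first)."""
        pa = self.links.pop(("end", end_a))
        if pa == ("end", end_b):
            raise ValueError(
                f"welding {end_a} to {end_b} would close a crossing-free loop"
            )
        pb = self.links.pop(("end", end_b))
        del self.links[pa], self.links[pb]
        if pa[0] == "end" or pb[0] == "end":
            raise ValueError("welding through a crossing-free strand")
        self.connect(pa, pb)
        return (pa, pb)

    def absorb(self, other: "OpenDiagram") -> dict[str, str]:
        """Copy ``other`` into self with fresh crossing ids and uniquified
        end names; returns the end-name mapping."""
        offset = self.n_crossings
        self.over_02.extend(other.over_02)
        self.labels.extend(other.labels)
        mapping = {}
        for name in other.ends():
            fresh = f"{name}#{offset}.{len(mapping)}"
            mapping[name] = fresh

        def conv(p: Plug) -> Plug:
            if p[0] == "x":
                return ("x", p[1] + offset, p[2])
            return ("end", mapping[p[1]])

        for a, b in other.links.items():
            self.links[conv(a)] = conv(b)
        return mapping


# --------------------------------------------------------------------------
# Sealed diagrams


@dataclass(frozen=True)
class PDCrossing:
    """PD-code crossing: incident arc labels counterclockwise starting at
    the incoming under-strand, plus the crossing sign."""

    arcs: tuple[int, int, int, int]
    sign: int
    label: Optional[str] = None


@dataclass
class Diagram:
    """An oriented single-component knot diagram of a sealed complex."""

    crossings: list[PDCrossing]

    @property
    def n_crossings(self) -> int:
        return len(self.crossings)

    def writhe(self) -> int:
        return sum(c.sign for c in self.crossings)

    def pd_code(self) -> str:
        return " ".join(
            "X[%d,%d,%d,%d]" % c.arcs for c in self.crossings
        )

    def gauss_code(self) -> str:
        """Signed, oriented Gauss code O/U per passage."""
        passages = []
        for i, c in enumerate(self.crossings, start=1):
            a, _, cc, _ = c.arcs
            # under passage enters on arc a; over passage enters on the arc
            # at position 1 or 3 depending on sign.
            over_in = c.arcs[3] if c.sign > 0 else c.arcs[1]
            passages.append((a, f"U{i}{'+' if c.sign > 0 else '-'}"))
            passages.append((over_in, f"O{i}{'+' if c.sign > 0 else '-'}"))
        return " ".join(tok for _, tok in sorted(passages))

    def mirror(self) -> "Diagram":
        """The mirror diagram (every crossing switched)."""
        out = []
        for c in self.crossings:
            a, b, cc, d = c.arcs
            # Switching over/under makes the old over-in arc the new
            # under-in; relist counterclockwise from there and flip sign.
            if c.sign > 0:
                out.append(PDCrossing((d, a, b, cc), -1, c.label))
            else:
                out.append(PDCrossing((b, cc, d, a), 1, c.label))
        return Diagram(out)


def writhe(d: Diagram) -> int:
    """Sum of crossing signs of an oriented diagram."""
    return d.writhe()


class TraversalError(RuntimeError):
    pass


def close_and_orient(diag: OpenDiagram, start_end: str = "W") -> Diagram:
    """Seal an open diagram (weld its two remaining ends) and orient it.

    The traversal starts on the sealing arc at the former ``start_end``
    endpoint, so arc 1 is the first arc of the oriented knot after the
    seal.  Raises if the diagram is not a single closed component or fails
    the planarity (Euler formula) check.
    """
    ends = diag.ends()
    if len(ends) != 2:
        raise TraversalError(f"expected 2 free ends, found {sorted(ends)}")
    other = (ends - {start_end}).pop() if start_end in ends else None
    if other is None:
        raise TraversalError(f"no end named {start_end!r}")
    start_plug = diag.partner_of_end(start_end)
    arc_pair = diag.weld(other, start_end)
    try:
        return _orient(diag, start_plug)
    finally:
        # restore openness so the caller's diagram is unchanged
        diag.disconnect(*arc_pair)
        diag.links[("end", start_end)] = start_plug
        diag.links[start_plug] = ("end", start_end)
        pb = arc_pair[0]
        diag.links[("end", other)] = pb
        diag.links[pb] = ("end", other)


def orient_closed(diag: OpenDiagram, start_plug: Optional[Plug] = None) -> Diagram:
    """Orient a fully closed diagram (no free ends), e.g. a braid closure."""
    if diag.ends():
        raise TraversalError(f"diagram has free ends: {sorted(diag.ends())}")
    if start_plug is None:
        start_plug = ("x", 0, 0)
    return _orient(diag, start_plug)


def _orient(diag: OpenDiagram, start_plug: Plug) -> Diagram:
    n = diag.n_crossings
    if n == 0:
        raise TraversalError("crossingless diagram (unknot); nothing to orient")
    # Traverse: enter a crossing at a port, leave at the opposite port,
    # follow the link to the next entry port.
    entries: dict[int, list[int]] = {}
    edge_of_entry: dict[tuple[int, int], int] = {}
    pos = start_plug
    edge = 1
    for _ in range(2 * n + 1):
        if pos[0] != "x":
            raise TraversalError("traversal escaped through a free end")
        _, cid, port = pos
        edge_of_entry[(cid, port)] = edge
        entries.setdefault(cid, []).append(port)
        out = ("x", cid, (port + 2) % 4)
        nxt = diag.links.get(out)
        if nxt is None:
            raise TraversalError(f"dangling plug {out!r}")
        if nxt == start_plug:
            break
        pos = nxt
        edge += 1
    else:
        raise TraversalError("traversal did not close up")
    if edge != 2 * n:
        raise TraversalError(
            f"closed after {edge} edges; diagram has more than one component"
        )
    total_edges = 2 * n

    crossings = []
    for cid in range(n):
        ports_in = entries.get(cid, [])
        if len(ports_in) != 2:
            raise TraversalError(f"crossing {cid} visited {len(ports_in)} times")
        p, q = ports_in
        over_ports = (0, 2) if diag.over_02[cid] else (1, 3)
        p_over = p if p in over_ports else q
        p_under = q if p in over_ports else p
        if p_over == p_under or (p_under in over_ports):
            raise TraversalError(f"crossing {cid} strand mismatch")
        sign = 1 if (p_over - p_under) % 4 == 3 else -1

        def arc_at(port: int) -> int:
            if (cid, port) in edge_of_entry:
                return edge_of_entry[(cid, port)]
            # outgoing port: its arc is the edge entering the far side plug
            far = diag.links[("x", cid, port)]
            if far[0] != "x":
                raise TraversalError("dangling arc")
            e = edge_of_entry[(far[1], far[2])]
            return e

        quad = tuple(arc_at((p_under + k) % 4) for k in range(4))
        crossings.append(PDCrossing(quad, sign, diag.labels[cid]))

    d = Diagram(crossings)
    _check_planar(diag, n, total_edges)
    return d


def _check_planar(diag: OpenDiagram, n: int, total_edges: int) -> None:
    """Euler-formula check on the closed 4-valent graph's rotation system."""
    # darts: (cid, port, outgoing?) -> face tracing: follow edge, then turn
    # to the next port clockwise at the destination.
    unused = set()
    for cid in range(n):
        for port in range(4):
            unused.add((cid, port))
    faces = 0
    # face-next: from an arrival at (cid, port): the next dart leaves from
    # port-1 (mod 4), i.e. turn clockwise.
    arrival_next = {}
    for cid in range(n):
        for port in range(4):
            arrival_next[(cid, port)] = (cid, (port - 1) % 4)
    while unused:
        start = unused.pop()
        cur = start
        for _ in range(8 * n + 1):
            dest = diag.links[("x", cur[0], cur[1])]
            if dest[0] != "x":
                raise TraversalError("open end during planarity check")
            nxt = arrival_next[(dest[1], dest[2])]
            if nxt == start:
                faces += 1
                break
            if nxt not in unused:
                raise TraversalError("face tracing error")
            unused.discard(nxt)
            cur = nxt
        else:
            raise TraversalError("unterminated face walk")
    euler = n - total_edges + faces
    if euler != 2:
        raise TraversalError(
            f"diagram is not planar: V-E+F = {n}-{total_edges}+{faces} = {euler}; "
            "a tile template or connector routing is inconsistent"
        )


# --------------------------------------------------------------------------
# Building complexes from templates




def _instantiate(diag, letter, tile, templates) -> dict[str, str]:
    if tile is None:
        raise ValueError(
            f"letter {letter!r} has no tile assigned; the diagram engine "
            "needs a full tile assignment"
        )
    tpl = templates[tile.canonical_label]
    mapping = diag.absorb(tpl)
    start = diag.n_crossings - tpl.n_crossings
    for cid in range(start, diag.n_crossings):
        diag.labels[cid] = letter
    return mapping


def _build(e: Expression, diag: OpenDiagram, templates) -> dict:
    """Recursively instantiate ``e``; returns {"W": end, "E": end,
    "arcs": {address: (upstream plug, downstream plug)}}."""
    if isinstance(e, Leaf1):
        ends = _instantiate(diag, e.letter, e.tile, templates)
        return {"W": ends["W"], "E": ends["E"], "arcs": {}}
    if isinstance(e, Closure):
        ends = _instantiate(diag, e.letter, e.tile, templates)
        up, down = diag.weld(ends["NW"], ends["NE"])
        return {"W": ends["SW"], "E": ends["SE"], "arcs": {("cl",): (up, down)}}
    if isinstance(e, Cross):
        ea = _instantiate(diag, e.letter_a, e.tile_a, templates)
        eb = _instantiate(diag, e.letter_b, e.tile_b, templates)
        t = diag.weld(ea["NW"], eb["NW"])
        m = diag.weld(eb["SW"], ea["NE"])
        b = diag.weld(ea["SE"], eb["SE"])
        return {
            "W": ea["SW"],
            "E": eb["NE"],
            "arcs": {("t",): t, ("m",): m, ("b",): b},
        }
    if isinstance(e, Series):
        left = _build(e.left, diag, templates)
        right = _build(e.right, diag, templates)
        conn = diag.weld(left["E"], right["W"])
        arcs = {("left",) + k: v for k, v in left["arcs"].items()}
        arcs[("conn",)] = conn
        arcs.update({("right",) + k: v for k, v in right["arcs"].items()})
        return {"W": left["W"], "E": right["E"], "arcs": arcs}
    if isinstance(e, Parallel):
        host = _build(e.host, diag, templates)
        ins = _build(e.inserted, diag, templates)
        site = tuple(e.site)
        up, down = host["arcs"].pop(site)
        diag.disconnect(up, down)
        w_plug = diag.links.pop(("end", ins["W"]))
        del diag.links[w_plug]
        e_plug = diag.links.pop(("end", ins["E"]))
        del diag.links[e_plug]
        diag.connect(up, w_plug)
        diag.connect(e_plug, down)
        arcs = host["arcs"]
        arcs[site + ("W",)] = (up, w_plug)
        arcs[site + ("E",)] = (e_plug, down)
        arcs.update({site + ("ins",) + k: v for k, v in ins["arcs"].items()})
        return {"W": host["W"], "E": host["E"], "arcs": arcs}
    raise TypeError(f"not an expression: {e!r}")


def build_sealed_diagram(e: Expression, templates) -> Diagram:
    """Sealed, oriented planar diagram of a tile complex.

    The sealing arc joins the W and E endpoints without crossings (they
    always lie in the same region); the result has a single closed
    component and exactly the sum of the tiles' template crossing counts.
    """
    violations = validate_expression(e)
    if violations:
        raise ValueError("invalid expression: " + "; ".join(violations))
    diag = OpenDiagram()
    built = _build(e, diag, templates)
    if built["W"] != "W":
        diag.rename_end(built["W"], "W")
    if built["E"] != "E":
        diag.rename_end(built["E"], "E")
    return close_and_orient(diag, start_end="W")
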