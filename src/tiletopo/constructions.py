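"""Reference diagram constructions: braid closures and rational knots.

These build the catalog's reference diagrams at load time, so every
catalog invariant is computed by the engine itself rather than shipped as
a constant.  Braid crossings and twist-region crossings are diagonal
4-valent vertices with ports listed counterclockwise as
[SW, SE, NE, NW] = [0, 1, 2, 3].
"""

from __future__ import annotations

from .diagrams import Diagram, OpenDiagram, orient_closed

__all__ = ["braid_closure", "rational_knot", "rational_tangle"]

SW, SE, NE, NW = 0, 1, 2, 3


def braid_closure(word: list[int], n_strands: int | None = None) -> Diagram:
    """Closure of a braid word (letters ±1, ±2, ... are signed generators).

    Strands run downward; the letter +i crosses strands i and i+1 with the
    strand entering at NW passing over (so +i is sigma_i).
    """
    if not word:
        raise ValueError("empty braid word")
    if n_strands is None:
        n_strands = max(abs(w) for w in word) + 1
    diag = OpenDiagram()
    # current[k] = the plug dangling at the bottom of strand position k
    current: list = [("end", f"top{k}") for k in range(n_strands)]
    for k in range(n_strands):
        diag.links[("end", f"top{k}")] = None  # placeholder
    for w in word:
        i = abs(w) - 1
        # over_02 flag: ports 0,2 = SW,NE carry the strand entering at NE;
        # ports 1,3 = SE,NW the strand entering at NW.  sigma_i (positive,
        # left-over) puts the NW-entering strand on top.
        cid = diag.add_crossing(over_02=(w < 0))
        _attach(diag, current[i], ("x", cid, NW))
        _attach(diag, current[i + 1], ("x", cid, NE))
        current[i] = ("x", cid, SW)
        current[i + 1] = ("x", cid, SE)
    for k in range(n_strands):
        top = diag.links.get(("end", f"top{k}"))
        del diag.links[("end", f"top{k}")]
        if top is None:
            raise ValueError(f"strand {k + 1} has no crossings")
        if diag.links.get(top) == ("end", f"top{k}"):
            del diag.links[top]
        diag.connect(current[k], top)
    return orient_closed(diag)


def _attach(diag: OpenDiagram, dangling, plug) -> None:
    """Connect a dangling bottom plug (or a top placeholder) to ``plug``."""
    if dangling[0] == "end":
        # first crossing on this strand: remember where the top attaches
        diag.links[dangling] = plug
        diag.links[plug] = dangling
    else:
        diag.connect(dangling, plug)


def rational_knot(cf: list[int], closure: str = "auto") -> Diagram:
    """Closure of the rational tangle with continued fraction ``cf``
    (built left-to-right: cf[0] is the innermost twist count).

    Twist counts alternate between horizontal twists (added on the east
    side) and vertical twists (added on the south side), arranged so the
    outermost region is horizontal; a negative count mirrors its twist
    region.  ``closure`` is ``numerator`` (join NW-NE and SW-SE),
    ``denominator`` (join NW-SW and NE-SE), or ``auto``: whichever yields
    a single component (exactly one of the two does for |fraction| > 1).
    """
    diag = _twist_tangle(cf, first="h")

    def strand_pairing() -> dict[str, str]:
        """Which boundary ends are joined by the tangle's strands."""
        pairing = {}
        for name in ("nw", "ne", "sw", "se"):
            if name in pairing:
                continue
            plug = diag.links[("end", name)]
            seen = 0
            while plug[0] == "x" and seen < 10 * diag.n_crossings:
                plug = diag.links[("x", plug[1], (plug[2] + 2) % 4)]
                seen += 1
            pairing[name] = plug[1]
            pairing[plug[1]] = name
        return pairing

    if closure == "auto":
        pairing = strand_pairing()
        # numerator closes nw-ne and sw-se; it yields one component
        # exactly when the tangle pairing is not {nw-ne, sw-se}
        closure = "denominator" if pairing["nw"] == "ne" else "numerator"
    if closure == "numerator":
        diag.weld("nw", "ne")
        diag.weld("sw", "se")
    elif closure == "denominator":
        diag.weld("nw", "sw")
        diag.weld("ne", "se")
    else:
        raise ValueError(f"unknown closure {closure!r}")
    return orient_closed(diag)


def _twist_tangle(cf: list[int], first: str) -> OpenDiagram:
    """Rational tangle built by alternating twist regions.

    Ends are named nw, ne, sw, se.  ``first`` is the direction of the
    cf[0] (innermost) twist region: "h" (east-side twists) or "v"
    (south-side twists).
    """
    diag = OpenDiagram()
    # start from the 0-tangle: nw-ne and sw-se joined by plain arcs
    diag.links[("end", "nw")] = ("end", "ne")
    diag.links[("end", "ne")] = ("end", "nw")
    diag.links[("end", "sw")] = ("end", "se")
    diag.links[("end", "se")] = ("end", "sw")

    def splice(name_a: str, name_b: str, plug_a, plug_b) -> None:
        """Replace boundary ends a, b by crossing plugs."""
        pa = diag.links.pop(("end", name_a))
        if pa == ("end", name_b):
            # the two boundary ends were directly joined; join the plugs
            del diag.links[("end", name_b)]
            diag.connect(plug_a, plug_b)
        else:
            del diag.links[pa]
            pb = diag.links.pop(("end", name_b))
            del diag.links[pb]
            diag.connect(pa, plug_a)
            diag.connect(pb, plug_b)

    def end_reset(name: str, plug) -> None:
        diag.links[("end", name)] = plug
        diag.links[plug] = ("end", name)

    horizontal = first == "h"
    for count in cf:
        for _ in range(abs(count)):
            if horizontal:
                # crossing east of the tangle: ne, se enter at NW, SW
                cid = diag.add_crossing(over_02=(count > 0))
                splice("ne", "se", ("x", cid, NW), ("x", cid, SW))
                end_reset("ne", ("x", cid, NE))
                end_reset("se", ("x", cid, SE))
            else:
                # crossing south of the tangle: sw, se enter at NW, NE
                cid = diag.add_crossing(over_02=(count > 0))
                splice("sw", "se", ("x", cid, NW), ("x", cid, NE))
                end_reset("sw", ("x", cid, SW))
                end_reset("se", ("x", cid, SE))
        horizontal = not horizontal
    return diag


def rational_tangle(cf: list[int], first: str = "h") -> OpenDiagram:
    """Open rational tangle with tile-style corner end names (NW, NE, SW,
    SE), usable as a 2-string tile template candidate."""
    diag = _twist_tangle(cf, first)
    for low, up in (("nw", "NW"), ("ne", "NE"), ("sw", "SW"), ("se", "SE")):
        diag.rename_end(low, up)
    return diag
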