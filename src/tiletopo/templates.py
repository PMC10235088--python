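"""Crossing templates for the five base tiles, and their transforms.

A template records, per strand of the tile, the ordered list of crossing
passages as ``[crossing, in_side, layer]``: ``in_side`` is the side the
strand enters the crossing from (S/E/N/W for an axis-aligned crossing,
SW/SE/NE/NW for a diagonal one, sides in counterclockwise order), and
``layer`` is ``o`` (over) or ``u`` (under).  Strand names fix the corner
endpoints: a 1-string tile has strand ``main`` from W to E; a 2-string
tile has strand ``west`` from SW to NW and strand ``east`` from SE to NE
(a chain segment enters and leaves a soft contact on the same side).

The base tiles:

* ``alpha`` — an open trefoil (cut closure of the braid sigma_1^3);
* ``beta`` — an open figure-eight (cut closure of (sigma_1 sigma_2^-1)^2);
* ``delta`` — a hook clasped through a loop (2 crossings);
* ``epsilon`` — a once-twisted hook through a loop (3 crossings);
* ``gamma`` — a twice-twisted hook through a loop (4 crossings).

The drawings these lists transcribe cannot be restated here; their
correctness is operational: the engine must reproduce the published
cross-products table and the basic sealing classes, and the test suite
gates the fixture on exactly that.

Transforming a template by a rectangle symmetry renames corners by the
in-plane corner permutation, reverses the counterclockwise port order when
the in-plane part is a reflection, and swaps over/under layers when the
symmetry flips the projection axis; knot handedness then flips exactly for
the orientation-reversing isometries.
"""

from __future__ import annotations

import importlib.resources as resources
from functools import lru_cache

import yaml

from .diagrams import OpenDiagram
from .symmetry import SymmetryElement
from .tiles import ALL_TILES, corner_permutation

__all__ = [
    "load_base_templates",
    "load_tile_templates",
    "transform_template",
    "TemplateError",
]

_AXIS = {"S": 0, "E": 1, "N": 2, "W": 3}
_DIAG = {"SW": 0, "SE": 1, "NE": 2, "NW": 3}

_STRAND_ENDS = {
    "main": ("W", "E"),
    "west": ("SW", "NW"),
    "east": ("SE", "NE"),
}


class TemplateError(ValueError):
    """Malformed tile-template fixture."""


def _template_from_spec(name: str, spec: dict) -> OpenDiagram:
    try:
        arity = spec["arity"]
        strands = spec["strands"]
    except (KeyError, TypeError):
        raise TemplateError(f"tile {name}: need 'arity' and 'strands'") from None
    expected = {"main"} if arity == 1 else {"west", "east"}
    if set(strands) != expected:
        raise TemplateError(
            f"tile {name}: arity {arity} needs strands {sorted(expected)}, "
            f"got {sorted(strands)}"
        )
    diag = OpenDiagram()
    cid_of: dict[str, int] = {}
    sides_seen: dict[str, list[tuple[int, str]]] = {}
    passages: dict[str, list[tuple[int, int]]] = {s: [] for s in strands}

    for sname, plist in strands.items():
        for item in plist:
            try:
                cname, side, layer = item
            except (TypeError, ValueError):
                raise TemplateError(
                    f"tile {name}: passage {item!r} must be "
                    "[crossing, in_side, layer]"
                ) from None
            if side not in _AXIS and side not in _DIAG:
                raise TemplateError(f"tile {name}: unknown side {side!r}")
            if layer not in ("o", "u"):
                raise TemplateError(f"tile {name}: layer must be 'o' or 'u'")
            if cname not in cid_of:
                cid_of[cname] = diag.add_crossing(over_02=False)
                sides_seen[cname] = []
            table = _AXIS if side in _AXIS else _DIAG
            port = table[side]
            passages[sname].append((cid_of[cname], port))
            if layer == "o":
                diag.over_02[cid_of[cname]] = port in (0, 2)
            sides_seen[cname].append((port, layer))

    # consistency: each crossing crossed exactly twice, on opposite axes,
    # with opposite layers
    for cname, rec in sides_seen.items():
        if len(rec) != 2:
            raise TemplateError(
                f"tile {name}: crossing {cname} has {len(rec)} passages"
            )
        (p1, l1), (p2, l2) = rec
        if (p1 - p2) % 2 == 0:
            raise TemplateError(
                f"tile {name}: crossing {cname} passages must use "
                "perpendicular in-sides"
            )
        if l1 == l2:
            raise TemplateError(
                f"tile {name}: crossing {cname} must have one over and one "
                "under passage"
            )

    for sname, plist in passages.items():
        start, end = _STRAND_ENDS[sname]
        prev = ("end", start)
        for cid, port in plist:
            diag.connect(prev, ("x", cid, port))
            prev = ("x", cid, (port + 2) % 4)
        diag.connect(prev, ("end", end))
    return diag


@lru_cache(maxsize=None)
def _load_fixture(path: str | None) -> dict:
    if path is None:
        text = (
            resources.files("tiletopo") / "data" / "tile_templates.yaml"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "tiles" not in data:
        raise TemplateError("fixture must be a mapping with a 'tiles' key")
    return data


def load_base_templates(path: str | None = None) -> dict[str, OpenDiagram]:
    """Templates of the five base tiles from the fixture file."""
    data = _load_fixture(path)
    tiles = data["tiles"]
    missing = {"alpha", "beta", "delta", "epsilon", "gamma"} - set(tiles)
    if missing:
        raise TemplateError(f"fixture lacks tile(s): {sorted(missing)}")
    return {
        name: _template_from_spec(name, spec) for name, spec in tiles.items()
    }


def transform_template(tpl: OpenDiagram, g: SymmetryElement) -> OpenDiagram:
    """Apply a rectangle symmetry to a template diagram."""
    reflect = g.reflects_plane
    flip = g.flips_z
    out = OpenDiagram()
    out.over_02 = [o ^ flip for o in tpl.over_02]
    out.labels = list(tpl.labels)
    perm = corner_permutation(g)
    swap_we = g.sign_vector[0] == -1
    end_map = dict(perm)
    end_map["W"], end_map["E"] = ("E", "W") if swap_we else ("W", "E")

    def conv(p):
        if p[0] == "x":
            port = (4 - p[2]) % 4 if reflect else p[2]
            return ("x", p[1], port)
        return ("end", end_map.get(p[1], p[1]))

    for a, b in tpl.links.items():
        out.links[conv(a)] = conv(b)
    return out


def load_tile_templates(path: str | None = None) -> dict[str, OpenDiagram]:
    """Templates for all 16 allowed tiles.

    Each canonical tile's template is the base family template transformed
    by the tile's coset representative.  The returned mapping feeds
    :func:`tiletopo.diagrams.build_sealed_diagram`.
    """
    base = load_base_templates(path)
    out: dict[str, OpenDiagram] = {}
    for t in ALL_TILES:
        out[t.canonical_label] = transform_template(
            base[t.family.name], t.representative
        )
    return out
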