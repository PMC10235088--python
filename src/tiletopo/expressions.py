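"""Operation-notation expression trees for tile complexes.

A tile complex is a projection of one oriented entangled arc built from
tiles joined by crossing-free planar arcs.  The four ways of building are:

* ``Leaf1`` — a single 1-string tile (the trivial complex);
* ``Closure`` — a 2-string tile with its NE and NW endpoints joined;
* ``Cross`` — two 2-string tiles joined by three connector arcs (top,
  middle, bottom) so the traversal alternates A, B, A, B;
* ``Series`` — two complexes concatenated end to end;
* ``Parallel`` — one complex spliced into an interior, tile-free arc of
  another.

Interior tile-free arcs are addressed by an :data:`ArcAddress`: a tuple of
steps descending the tree, ending in an arc selector (``cl`` for the closure
arc, ``t``/``m``/``b`` for the cross connectors, ``conn`` for a series
connector, ``W``/``E`` for the two halves of an arc that received an
insertion, ``ins`` to descend into an inserted complex).  The two
endpoint-bearing arcs of a complex are never insertable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Optional, Union

from .tiles import Tile

ArcAddress = tuple[str, ...]

__all__ = [
    "Expression",
    "Leaf1",
    "Closure",
    "Cross",
    "Series",
    "Parallel",
    "ArcAddress",
    "traversal_tokens",
    "to_sequence_letters",
    "list_insertable_arcs",
    "letters_of",
    "tile_assignment",
    "validate_expression",
    "insert",
    "series_summands",
]


@dataclass(frozen=True)
class Leaf1:
    """A single 1-string tile occurrence named by ``letter``."""

    letter: str
    tile: Optional[Tile] = None


@dataclass(frozen=True)
class Closure:
    """Closure of a 2-string tile: NE and NW endpoints joined by an arc."""

    letter: str
    tile: Optional[Tile] = None


@dataclass(frozen=True)
class Cross:
    """Cross of two 2-string tiles; traversal alternates A, B, A, B.

    The three connector arcs are named ``t`` (between the first visits of A
    and B), ``m`` (between the first B and the second A) and ``b`` (between
    the second A and the second B).
    """

    letter_a: str
    letter_b: str
    tile_a: Optional[Tile] = None
    tile_b: Optional[Tile] = None


@dataclass(frozen=True)
class Series:
    left: "Expression"
    right: "Expression"


@dataclass(frozen=True)
class Parallel:
    host: "Expression"
    inserted: "Expression"
    site: ArcAddress


Expression = Union[Leaf1, Closure, Cross, Series, Parallel]

# Letter occurrences are identified as (letter, k) with k the 1-based visit
# number along the traversal; arcs appear as ("arc", address) tokens.
Token = tuple[str, object]


def traversal_tokens(e: Expression) -> list[Token]:
    """Oriented W-to-E traversal as alternating letter and arc tokens.

    Letters and interior tile-free arcs strictly alternate; the endpoint
    arcs at the two ends are omitted.
    """
    if isinstance(e, Leaf1):
        return [("letter", e.letter)]
    if isinstance(e, Closure):
        return [("letter", e.letter), ("arc", ("cl",)), ("letter", e.letter)]
    if isinstance(e, Cross):
        a, b = e.letter_a, e.letter_b
        return [
            ("letter", a),
            ("arc", ("t",)),
            ("letter", b),
            ("arc", ("m",)),
            ("letter", a),
            ("arc", ("b",)),
            ("letter", b),
        ]
    if isinstance(e, Series):
        left = [_prefix(tok, "left") for tok in traversal_tokens(e.left)]
        right = [_prefix(tok, "right") for tok in traversal_tokens(e.right)]
        return left + [("arc", ("conn",))] + right
    if isinstance(e, Parallel):
        host = traversal_tokens(e.host)
        inner = traversal_tokens(e.inserted)
        site = tuple(e.site)
        out: list[Token] = []
        found = False
        for tok in host:
            if tok == ("arc", site):
                found = True
                out.append(("arc", site + ("W",)))
                for itok in inner:
                    if itok[0] == "arc":
                        out.append(("arc", site + ("ins",) + itok[1]))
                    else:
                        out.append(itok)
                out.append(("arc", site + ("E",)))
            else:
                out.append(tok)
        if not found:
            raise ValueError(
                f"parallel site {site!r} is not an insertable arc of its host"
            )
        return out
    raise TypeError(f"not an expression: {e!r}")


def _prefix(tok: Token, step: str) -> Token:
    if tok[0] == "arc":
        return ("arc", (step,) + tok[1])
    return tok


def to_sequence_letters(e: Expression) -> tuple[str, ...]:
    """The traversal sequence of tile letters from W to E."""
    return tuple(t[1] for t in traversal_tokens(e) if t[0] == "letter")


def list_insertable_arcs(e: Expression) -> list[ArcAddress]:
    """All tile-free interior arcs in oriented-traversal order."""
    return [t[1] for t in traversal_tokens(e) if t[0] == "arc"]


def _occurrences(e: Expression) -> Iterator[tuple[str, Optional[Tile], int]]:
    """(letter, tile, n_strings_expected) per tile occurrence site."""
    if isinstance(e, Leaf1):
        yield (e.letter, e.tile, 1)
    elif isinstance(e, Closure):
        yield (e.letter, e.tile, 2)
    elif isinstance(e, Cross):
        yield (e.letter_a, e.tile_a, 2)
        yield (e.letter_b, e.tile_b, 2)
    elif isinstance(e, Series):
        yield from _occurrences(e.left)
        yield from _occurrences(e.right)
    elif isinstance(e, Parallel):
        yield from _occurrences(e.host)
        yield from _occurrences(e.inserted)
    else:
        raise TypeError(f"not an expression: {e!r}")


def letters_of(e: Expression) -> list[str]:
    return [letter for letter, _, _ in _occurrences(e)]


def tile_assignment(e: Expression) -> dict[str, Optional[Tile]]:
    return {letter: tile for letter, tile, _ in _occurrences(e)}


def validate_expression(e: Expression) -> list[str]:
    """All invariant violations of ``e`` (empty list means valid).

    Checks: closure/cross apply only to 2-string tiles and Leaf1 only to
    1-string tiles; each letter names exactly one tile occurrence; every
    parallel site resolves to an insertable arc of its host.
    """
    violations: list[str] = []
    seen: set[str] = set()
    try:
        occs = list(_occurrences(e))
    except TypeError as err:
        return [str(err)]
    for letter, t, arity in occs:
        if letter in seen:
            violations.append(f"letter {letter!r} names more than one tile")
        seen.add(letter)
        if t is not None and t.arity != arity:
            kind = "closure/cross" if arity == 2 else "a 1-string leaf"
            violations.append(
                f"tile {t.canonical_label} (arity {t.arity}) used as {kind}"
            )

    def walk(node: Expression) -> None:
        if isinstance(node, Series):
            walk(node.left)
            walk(node.right)
        elif isinstance(node, Parallel):
            host_arcs = set(list_insertable_arcs(node.host))
            if tuple(node.site) not in host_arcs:
                violations.append(
                    f"parallel site {node.site!r} is not an insertable arc "
                    "of its host"
                )
                return
            walk(node.host)
            walk(node.inserted)

    walk(e)
    return violations


def series_summands(e: Expression) -> list[Expression]:
    """Flatten a left/right-nested series chain into its summands."""
    if isinstance(e, Series):
        return series_summands(e.left) + series_summands(e.right)
    return [e]


def _series_of(parts: list[Expression]) -> Expression:
    expr = parts[0]
    for p in parts[1:]:
        expr = Series(expr, p)
    return expr


def insert(host: Expression, x: Expression, arc: ArcAddress) -> Expression:
    """Insert complex ``x`` into the interior arc ``arc`` of ``host``.

    The result is normalised the way the sequence algorithm draws it:
    insertion into a series connector becomes a new series summand,
    insertion into the W/E half of an already-occupied arc extends the
    occupying complex in series, and insertion elsewhere becomes a parallel
    node whose site is an immediate arc of its host.
    """
    arc = tuple(arc)
    if isinstance(host, Series):
        if arc == ("conn",):
            parts = series_summands(host.left) + [x] + series_summands(host.right)
            return _series_of(parts)
        if arc and arc[0] in ("left", "right"):
            if arc[0] == "left":
                return replace(host, left=insert(host.left, x, arc[1:]))
            return replace(host, right=insert(host.right, x, arc[1:]))
        raise ValueError(f"arc {arc!r} does not exist in a series")
    if isinstance(host, Parallel):
        site = tuple(host.site)
        if arc == site + ("W",):
            return replace(host, inserted=_series_of([x] + series_summands(host.inserted)))
        if arc == site + ("E",):
            return replace(host, inserted=_series_of(series_summands(host.inserted) + [x]))
        if arc[: len(site) + 1] == site + ("ins",):
            return replace(host, inserted=insert(host.inserted, x, arc[len(site) + 1:]))
        return replace(host, host=insert(host.host, x, arc))
    # Closure / Cross hosts: arc must be one of their own connector arcs.
    if arc not in set(list_insertable_arcs(host)):
        raise ValueError(f"arc {arc!r} does not exist in {host!r}")
    return Parallel(host, x, arc)
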