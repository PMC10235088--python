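"""ASCII grammar for operation notation.

The mathematical notation (overlines, ×, ∥ with subscripts) is transliterated
to a lossless, typeable ASCII form::

    closure    cl(A)
    cross      (A x B)
    series     S + T
    parallel   S || T        (host has a unique insertable arc)
               S ||_b T      (site suffix: _t, _m, _b on a cross host;
                              _W, _E on a parallel host)

Tile occurrences are written as a bare capital letter (``A``, unassigned),
a tile name (``delta``, letter assigned automatically in traversal order),
or both (``A=delta``).  The canonical printer always names letters
explicitly, so bare tile names are parse-time sugar.

Series and parallel associate to the left; compound operands are always
parenthesised by the printer, e.g. ``((A x B) ||_b (cl(D) + E)) + (cl(C) || F)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .expressions import (
    Closure,
    Cross,
    Expression,
    Leaf1,
    Parallel,
    Series,
    list_insertable_arcs,
    traversal_tokens,
)
from .tiles import Tile, tile as lookup_tile, _TILE_BY_LABEL

__all__ = ["parse_operation_notation", "format_operation_notation", "NotationError"]


class NotationError(ValueError):
    """Syntax or arity error in operation notation, with position."""

    def __init__(self, message: str, pos: int | None = None):
        self.pos = pos
        suffix = f" (at position {pos})" if pos is not None else ""
        super().__init__(message + suffix)


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<par>\|\|(?:_[WEbmt])?)"
    r"|(?P<plus>\+)"
    r"|(?P<lpar>\()"
    r"|(?P<rpar>\))"
    r"|(?P<eq>=)"
    r"|(?P<ident>[A-Za-z][A-Za-z0-9_*]*))"
)


@dataclass
class _Tok:
    kind: str
    value: str
    pos: int


def _tokenize(text: str) -> list[_Tok]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip() == "":
                break
            raise NotationError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        tokens.append(_Tok(kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.toks = _tokenize(text)
        self.i = 0
        self._auto = 0

    def peek(self) -> _Tok | None:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self) -> _Tok:
        tok = self.peek()
        if tok is None:
            raise NotationError("unexpected end of input", len(self.text))
        self.i += 1
        return tok

    def expect(self, kind: str) -> _Tok:
        tok = self.next()
        if tok.kind != kind:
            raise NotationError(f"expected {kind}, found {tok.value!r}", tok.pos)
        return tok

    # -- atoms -----------------------------------------------------------
    def _fresh_placeholder(self) -> str:
        self._auto += 1
        return f"\x00{self._auto}"

    def parse_atom(self, arity: int) -> tuple[str, Tile | None]:
        tok = self.expect("ident")
        name = tok.value
        tile: Tile | None = None
        letter: str | None = None
        if name in _TILE_BY_LABEL:
            tile = lookup_tile(name)
            letter = self._fresh_placeholder()
        elif re.fullmatch(r"[A-Z]", name):
            letter = name
        else:
            raise NotationError(
                f"{name!r} is neither a capital letter nor a tile name", tok.pos
            )
        if self.peek() is not None and self.peek().kind == "eq":
            if tile is not None:
                raise NotationError("letter must precede '=' in an assignment", tok.pos)
            self.next()
            tname = self.expect("ident")
            try:
                tile = lookup_tile(tname.value)
            except ValueError as err:
                raise NotationError(str(err), tname.pos) from None
        if tile is not None and tile.arity != arity:
            raise NotationError(
                f"tile {tile.canonical_label} has {tile.arity} string(s); "
                f"this position requires {arity}",
                tok.pos,
            )
        return letter, tile

    def _looks_like_cross(self) -> bool:
        """After '(', do the tokens read ``atom x atom )``?"""
        j = self.i
        toks = self.toks
        if j >= len(toks) or toks[j].kind != "ident" or toks[j].value == "cl":
            return False
        j += 1
        if j + 1 < len(toks) and toks[j].kind == "eq":
            if toks[j + 1].kind != "ident":
                return False
            j += 2
        return j < len(toks) and toks[j].kind == "ident" and toks[j].value == "x"

    # -- expressions -----------------------------------------------------
    def parse_term(self) -> Expression:
        tok = self.peek()
        if tok is None:
            raise NotationError("unexpected end of input", len(self.text))
        if tok.kind == "ident" and tok.value == "cl":
            self.next()
            self.expect("lpar")
            letter, t = self.parse_atom(arity=2)
            self.expect("rpar")
            return Closure(letter, t)
        if tok.kind == "lpar":
            self.next()
            # Either a parenthesised cross "(A x B)" or a grouped expression;
            # decide by token shape so arity errors in a cross are reported
            # as such rather than as syntax errors.
            if self._looks_like_cross():
                la, ta = self.parse_atom(arity=2)
                self.next()  # the "x"
                lb, tb = self.parse_atom(arity=2)
                self.expect("rpar")
                return Cross(la, lb, ta, tb)
            e = self.parse_expr()
            self.expect("rpar")
            return e
        if tok.kind == "ident":
            letter, t = self.parse_atom(arity=1)
            return Leaf1(letter, t)
        raise NotationError(f"unexpected token {tok.value!r}", tok.pos)

    def parse_expr(self) -> Expression:
        node = self.parse_term()
        while True:
            tok = self.peek()
            if tok is None or tok.kind == "rpar":
                return node
            if tok.kind == "plus":
                self.next()
                node = Series(node, self.parse_term())
            elif tok.kind == "par":
                self.next()
                suffix = tok.value[3:] if len(tok.value) > 2 else None
                site = self._resolve_site(node, suffix, tok.pos)
                node = Parallel(node, self.parse_term(), site)
            else:
                raise NotationError(f"unexpected token {tok.value!r}", tok.pos)

    def _resolve_site(self, host, suffix, pos):
        arcs = list_insertable_arcs(host)
        if suffix is None:
            if len(arcs) != 1:
                raise NotationError(
                    "parallel without a site suffix requires a host with "
                    f"exactly one insertable arc (host has {len(arcs)})",
                    pos,
                )
            return arcs[0]
        if suffix in ("t", "m", "b"):
            if (suffix,) not in arcs:
                raise NotationError(
                    f"host has no arc {suffix!r} (not a cross?)", pos
                )
            return (suffix,)
        # suffix in ("W", "E"): the host must be a parallel; the site names
        # the half of the occupied arc west or east of the inserted complex.
        if not isinstance(host, Parallel):
            raise NotationError(
                f"site suffix _{suffix} requires a parallel host", pos
            )
        return tuple(host.site) + (suffix,)


def _assign_auto_letters(e: Expression) -> Expression:
    """Replace placeholder letters with unused capitals in traversal order."""
    order: list[str] = []
    for kind, val in traversal_tokens(e):
        if kind == "letter" and val not in order:
            order.append(val)
    explicit = {l for l in order if not l.startswith("\x00")}
    pool = (ch for ch in "ABCDEFGHIJKLMNOPQRSTUVWXYZ" if ch not in explicit)
    mapping: dict[str, str] = {}
    for letter in order:
        if letter.startswith("\x00"):
            try:
                mapping[letter] = next(pool)
            except StopIteration:
                raise NotationError("more than 26 tiles; name letters explicitly")
    if not mapping:
        return e

    def rename(node: Expression) -> Expression:
        if isinstance(node, Leaf1):
            return Leaf1(mapping.get(node.letter, node.letter), node.tile)
        if isinstance(node, Closure):
            return Closure(mapping.get(node.letter, node.letter), node.tile)
        if isinstance(node, Cross):
            return Cross(
                mapping.get(node.letter_a, node.letter_a),
                mapping.get(node.letter_b, node.letter_b),
                node.tile_a,
                node.tile_b,
            )
        if isinstance(node, Series):
            return Series(rename(node.left), rename(node.right))
        return Parallel(rename(node.host), rename(node.inserted), node.site)

    return rename(e)


def parse_operation_notation(text: str) -> Expression:
    """Parse ASCII operation notation into an expression tree."""
    parser = _Parser(text)
    expr = parser.parse_expr()
    tok = parser.peek()
    if tok is not None:
        raise NotationError(f"trailing input {tok.value!r}", tok.pos)
    expr = _assign_auto_letters(expr)
    from .expressions import validate_expression

    violations = validate_expression(expr)
    if violations:
        raise NotationError("; ".join(violations))
    return expr


def _atom_str(letter: str, t: Tile | None) -> str:
    return letter if t is None else f"{letter}={t.canonical_label}"


def _site_suffix(node: Parallel) -> str:
    host = node.host
    arcs = list_insertable_arcs(host)
    if len(arcs) == 1:
        return ""
    site = tuple(node.site)
    if site in (("t",), ("m",), ("b",)):
        return "_" + site[0]
    if isinstance(host, Parallel) and site[:-1] == tuple(host.site) and site[-1] in ("W", "E"):
        return "_" + site[-1]
    raise ValueError(
        f"site {site!r} is not expressible in operation notation; "
        "rebuild the expression with tiletopo.expressions.insert"
    )


def format_operation_notation(e: Expression) -> str:
    """Canonical ASCII form; ``parse(format(e))`` is structurally ``e``."""

    def wrap(node: Expression) -> str:
        s = format_operation_notation(node)
        if isinstance(node, (Series, Parallel)):
            return f"({s})"
        return s

    if isinstance(e, Leaf1):
        return _atom_str(e.letter, e.tile)
    if isinstance(e, Closure):
        return f"cl({_atom_str(e.letter, e.tile)})"
    if isinstance(e, Cross):
        return f"({_atom_str(e.letter_a, e.tile_a)} x {_atom_str(e.letter_b, e.tile_b)})"
    if isinstance(e, Series):
        # series chains are left-associative and print flat
        left = (
            format_operation_notation(e.left)
            if isinstance(e.left, Series)
            else wrap(e.left)
        )
        return f"{left} + {wrap(e.right)}"
    if isinstance(e, Parallel):
        return f"{wrap(e.host)} ||{_site_suffix(e)} {wrap(e.inserted)}"
    raise TypeError(f"not an expression: {e!r}")
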