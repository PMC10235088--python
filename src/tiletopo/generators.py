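"""Seeded random generators for property testing.

Expressions are grown by randomly applying the four operations over
randomly chosen allowed tiles; sequences are the traversals of random
expressions (every valid sequence is the traversal of its canonical
complex, so this samples the full language).  Identical configurations
yield identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .expressions import (
    Closure,
    Cross,
    Expression,
    Leaf1,
    Parallel,
    Series,
    insert,
    list_insertable_arcs,
    traversal_tokens,
)
from .sequences import Sequence, to_sequence
from .tiles import ALL_TILES

__all__ = ["GeneratorConfig", "random_expression", "random_valid_sequence"]

_ONE_STRING = tuple(t for t in sorted(ALL_TILES) if t.arity == 1)
_TWO_STRING = tuple(t for t in sorted(ALL_TILES) if t.arity == 2)
_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class GeneratorConfig:
    """Reproducible generator settings.

    ``n_tiles`` is the number of tile occurrences; ``p_two_string`` the
    probability that a grown basic complex is a closure rather than a
    1-string tile (crosses always use two 2-string tiles); ``max_depth``
    bounds the nesting depth of parallel insertions.
    """

    n_tiles: int = 5
    p_two_string: float = 0.6
    seed: int = 0
    max_depth: int = 4

    def __post_init__(self):
        if not 1 <= self.n_tiles <= 26:
            raise ValueError("n_tiles must be between 1 and 26")
        if not 0 <= self.p_two_string <= 1:
            raise ValueError("p_two_string must be a probability")
        if self.max_depth < 1:
            raise ValueError("max_depth must be positive")


def _random_basic(rng: random.Random, letters: list[str], budget: int, p_two: float):
    """A random basic complex costing at most ``budget`` tiles."""
    if budget >= 2 and rng.random() < 0.35:
        a, b = letters.pop(), letters.pop()
        return Cross(a, b, rng.choice(_TWO_STRING), rng.choice(_TWO_STRING))
    if rng.random() < p_two:
        return Closure(letters.pop(), rng.choice(_TWO_STRING))
    return Leaf1(letters.pop(), rng.choice(_ONE_STRING))


def random_expression(cfg: GeneratorConfig) -> Expression:
    """A random valid expression with ``cfg.n_tiles`` assigned tiles.

    Growth alternates series extension and parallel insertion into a
    random insertable arc (depth-bounded); letters are relabelled
    A, B, C, ... in order of first traversal appearance at the end.
    """
    rng = random.Random(cfg.seed)
    letters = list(reversed(_LETTERS[: cfg.n_tiles]))

    expr = _random_basic(rng, letters, cfg.n_tiles, cfg.p_two_string)
    while letters:
        budget = len(letters)
        piece = _random_basic(rng, letters, budget, cfg.p_two_string)
        arcs = [
            a
            for a in list_insertable_arcs(expr)
            if len(a) <= 2 * cfg.max_depth
        ]
        if arcs and rng.random() < 0.6:
            expr = insert(expr, piece, rng.choice(arcs))
        elif rng.random() < 0.5:
            expr = Series(expr, piece)
        else:
            expr = Series(piece, expr)
    return _relabel_traversal_order(expr)


def _relabel_traversal_order(e: Expression) -> Expression:
    order: list[str] = []
    for kind, val in traversal_tokens(e):
        if kind == "letter" and val not in order:
            order.append(val)
    mapping = {old: _LETTERS[i] for i, old in enumerate(order)}

    def rename(node: Expression) -> Expression:
        if isinstance(node, Leaf1):
            return Leaf1(mapping[node.letter], node.tile)
        if isinstance(node, Closure):
            return Closure(mapping[node.letter], node.tile)
        if isinstance(node, Cross):
            return Cross(
                mapping[node.letter_a], mapping[node.letter_b],
                node.tile_a, node.tile_b,
            )
        if isinstance(node, Series):
            return Series(rename(node.left), rename(node.right))
        return Parallel(rename(node.host), rename(node.inserted), node.site)

    return rename(e)


def random_valid_sequence(cfg: GeneratorConfig) -> Sequence:
    """A random sequence satisfying both validity requirements, with every
    letter assigned an allowed tile of matching arity."""
    return to_sequence(random_expression(cfg))
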