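"""Sequence notation and its conversion to operation notation.

The sequence of a tile complex is the list of tile letters met while
travelling along the oriented arc from its W endpoint to its E endpoint.
A letter string represents a tile complex exactly when

1. each letter appears once (a 1-string tile) or twice (a 2-string tile);
2. at most one letter alternates with a given letter, where letters X and Y
   alternate when their occurrences interleave as XYXY or YXYX.

A once-occurring letter is a *singleton*; adjacent equal letters ``XX`` are
*twins* (a closure); four adjacent alternating letters ``XYXY`` are an
*interweaving* (a cross).  Every nonempty singleton-free valid sequence
contains twins or an interweaving, so repeatedly deleting them terminates;
replaying the deletions in reverse rebuilds a tile complex and one
operation notation for the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .expressions import (
    Closure,
    Cross,
    Expression,
    Leaf1,
    Series,
    insert,
    to_sequence_letters,
    tile_assignment,
    traversal_tokens,
    validate_expression,
)
from .tiles import Tile

__all__ = [
    "Sequence",
    "validate_sequence",
    "find_singletons",
    "find_twins_and_interweavings",
    "reduce_once",
    "sequence_to_expression",
    "to_sequence",
    "complexes_equal",
]


@dataclass(frozen=True)
class Sequence:
    """An ordered list of tile letters with an optional tile assignment."""

    letters: tuple[str, ...]
    assignment: dict[str, Tile] = field(default_factory=dict, compare=False)

    @classmethod
    def from_string(cls, text: str, assignment: Optional[dict[str, Tile]] = None) -> "Sequence":
        return cls(tuple(text.strip()), dict(assignment or {}))

    def __str__(self) -> str:
        return "".join(self.letters)

    def __len__(self) -> int:
        return len(self.letters)


def _alternates(positions_x: list[int], positions_y: list[int]) -> bool:
    """Occurrences interleave as XYXY or YXYX (both letters twice)."""
    if len(positions_x) != 2 or len(positions_y) != 2:
        return False
    x1, x2 = positions_x
    y1, y2 = positions_y
    return (x1 < y1 < x2 < y2) or (y1 < x1 < y2 < x2)


def _positions(seq: Sequence) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = {}
    for i, ch in enumerate(seq.letters):
        pos.setdefault(ch, []).append(i)
    return pos


def validate_sequence(seq: Sequence) -> list[str]:
    """All violations of the two sequence requirements (empty means valid)."""
    violations: list[str] = []
    pos = _positions(seq)
    for letter, occ in pos.items():
        if len(occ) > 2:
            violations.append(
                f"Requirement 1: letter {letter!r} appears {len(occ)} times"
            )
    letters = sorted(pos)
    partners: dict[str, list[str]] = {l: [] for l in letters}
    for i, x in enumerate(letters):
        for y in letters[i + 1:]:
            if _alternates(pos[x], pos[y]):
                partners[x].append(y)
                partners[y].append(x)
    for letter in letters:
        if len(partners[letter]) > 1:
            violations.append(
                f"Requirement 2: {letter} alternates with "
                + " and ".join(partners[letter])
            )
    for letter, t in seq.assignment.items():
        n = len(pos.get(letter, []))
        if n and t.arity != n:
            violations.append(
                f"letter {letter} appears {n} time(s) but is assigned the "
                f"{t.arity}-string tile {t.canonical_label}"
            )
    return violations


def find_singletons(seq: Sequence) -> set[str]:
    """Letters appearing exactly once (they represent 1-string tiles)."""
    return {l for l, occ in _positions(seq).items() if len(occ) == 1}


@dataclass(frozen=True)
class Reducible:
    """A maximal deletable block: twins ``XX`` or an interweaving ``XYXY``."""

    kind: str  # "twins" | "interweaving"
    letters: tuple[str, ...]
    start: int  # position of the block in its sequence

    @property
    def span(self) -> int:
        return 2 if self.kind == "twins" else 4


def find_twins_and_interweavings(seq: Sequence) -> list[Reducible]:
    """All twins and interweavings, scanning once left to right.

    Alternating letters that are not adjacent (as in ABACCB) are not
    interweavings; they become adjacent only after inner deletions.
    """
    s = seq.letters
    blocks: list[Reducible] = []
    i = 0
    while i < len(s):
        if (
            i + 3 < len(s)
            and s[i] != s[i + 1]
            and s[i] == s[i + 2]
            and s[i + 1] == s[i + 3]
        ):
            blocks.append(Reducible("interweaving", (s[i], s[i + 1]), i))
            i += 4
        elif i + 1 < len(s) and s[i] == s[i + 1]:
            blocks.append(Reducible("twins", (s[i],), i))
            i += 2
        else:
            i += 1
    return blocks


def reduce_once(seq: Sequence) -> tuple[Sequence, list[Reducible]]:
    """Delete all twins and interweavings found in one scan.

    The output is strictly shorter for any nonempty valid singleton-free
    input; failure to find a block in such input signals a validator bug,
    since a valid singleton-free sequence always contains one.
    """
    blocks = find_twins_and_interweavings(seq)
    if not blocks:
        if len(seq):
            raise AssertionError(
                f"no twins or interweaving in nonempty singleton-free "
                f"sequence {seq} — validator bug"
            )
        return seq, []
    drop = set()
    for b in blocks:
        drop.update(range(b.start, b.start + b.span))
    remaining = tuple(ch for i, ch in enumerate(seq.letters) if i not in drop)
    return Sequence(remaining, seq.assignment), blocks


def _block_expression(block: Reducible, assignment: dict[str, Tile]) -> Expression:
    if block.kind == "twins":
        (x,) = block.letters
        return Closure(x, assignment.get(x))
    x, y = block.letters
    return Cross(x, y, assignment.get(x), assignment.get(y))


def _insert_at_index(expr: Optional[Expression], x: Expression, idx: int) -> Expression:
    """Insert complex ``x`` so its letters start at traversal position ``idx``."""
    if expr is None:
        return x
    tokens = traversal_tokens(expr)
    letter_count = sum(1 for t in tokens if t[0] == "letter")
    if idx == 0:
        return Series(x, expr)
    if idx == letter_count:
        return Series(expr, x)
    # The arc between traversal letters idx-1 and idx: tokens alternate
    # letter, arc, letter, ... so it sits at token position 2*idx - 1.
    kind, arc = tokens[2 * idx - 1]
    assert kind == "arc", "traversal tokens must alternate letters and arcs"
    return insert(expr, x, arc)


def sequence_to_expression(seq: Sequence) -> Expression:
    """One operation notation for a valid sequence.

    Implements the deletion/replay algorithm: strip singletons, repeatedly
    delete twins and interweavings until empty, then rebuild — the last
    nonempty sequence becomes a series of closures and crosses, each earlier
    deletion is re-inserted at the unique arc between its flanking
    traversal positions, and singletons are re-inserted last.  The result
    always traverses back to the input sequence.
    """
    violations = validate_sequence(seq)
    if violations:
        raise ValueError("invalid sequence: " + "; ".join(violations))
    assignment = dict(seq.assignment)

    # Step 1: strip singletons, remembering their positions in the input.
    singles = find_singletons(seq)
    singleton_records = [
        (i, ch) for i, ch in enumerate(seq.letters) if ch in singles
    ]
    s1 = Sequence(tuple(ch for ch in seq.letters if ch not in singles), assignment)

    # Steps 2-3: reduce to the empty sequence, recording each pass.
    passes: list[tuple[Sequence, list[Reducible]]] = []
    current = s1
    while len(current):
        shorter, blocks = reduce_once(current)
        passes.append((current, blocks))
        current = shorter

    expr: Optional[Expression] = None
    if passes:
        # Steps 4-5: the last nonempty sequence is a series of its blocks.
        _, last_blocks = passes[-1]
        for block in last_blocks:
            piece = _block_expression(block, assignment)
            expr = piece if expr is None else Series(expr, piece)
        # Steps 6-7: replay earlier deletions, innermost last.
        for parent, blocks in reversed(passes[:-1]):
            for block in blocks:
                expr = _insert_at_index(
                    expr, _block_expression(block, assignment), block.start
                )
    # Step 8: re-insert singletons at their recorded positions.  Processing
    # left to right, every input letter before position idx (singleton or
    # not) is already present, so the insertion index is idx itself.
    for idx, ch in singleton_records:
        expr = _insert_at_index(expr, Leaf1(ch, assignment.get(ch)), idx)

    assert expr is not None or len(seq) == 0
    if expr is None:
        raise ValueError("the empty sequence has no tile complex")
    assert to_sequence_letters(expr) == seq.letters, (
        "rebuilt complex does not traverse to its own sequence"
    )
    return expr


def to_sequence(e: Expression) -> Sequence:
    """The unique traversal sequence of a valid expression."""
    violations = validate_expression(e)
    if violations:
        raise ValueError("invalid expression: " + "; ".join(violations))
    letters = to_sequence_letters(e)
    assignment = {l: t for l, t in tile_assignment(e).items() if t is not None}
    return Sequence(letters, assignment)


def canonical_form(e: Expression) -> Expression:
    """The expression the sequence algorithm rebuilds from ``e``'s sequence."""
    return sequence_to_expression(to_sequence(e))


def complexes_equal(s: Expression, t: Expression) -> bool:
    """Tile-complex equality decided via sequence canonicalization.

    Two complexes are compared by converting each to its traversal sequence
    and rebuilding the canonical expression; letters and tile assignments
    are compared verbatim.
    """
    return canonical_form(s) == canonical_form(t)
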