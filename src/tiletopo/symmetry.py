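"""Rectangle symmetry group acting on tiles.

A tile is a rigid rectangle in the projection plane.  Its symmetries are the
identity, the three 180-degree rotations about the x- (long), y- (short) and
z- (normal) axes, the two in-plane mirror reflections across the yz- and
xz-planes, the reflection across the plane of the paper (the ``*`` or mirror
operation) and the point inversion.  Together they form the group
(Z/2)^3, faithfully represented by sign vectors acting on the coordinate
axes: composition is componentwise sign multiplication.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "SymmetryElement",
    "ELEMENTS",
    "E",
    "RX",
    "RY",
    "RZ",
    "MV",
    "MH",
    "MSTAR",
    "INV",
    "compose_symmetry",
    "element",
]


@dataclass(frozen=True, order=True)
class SymmetryElement:
    """One of the eight rigid symmetries of a rectangle.

    ``sign_vector`` records the action on the (x, y, z) axes, e.g. the
    rotation about x fixes x and negates y and z.  Useful derived facts:

    * ``flips_z`` — the element exchanges over- and under-strands of a
      projected tangle (it reverses the projection direction);
    * ``reflects_plane`` — the induced map on the projection plane is a
      reflection (determinant -1), so it reverses the counterclockwise
      rotation order around a crossing;
    * ``reverses_orientation`` — the 3-space isometry is orientation
      reversing, which is exactly when it mirrors knot handedness.
    """

    label: str
    sign_vector: tuple[int, int, int]

    @property
    def flips_z(self) -> bool:
        return self.sign_vector[2] == -1

    @property
    def reflects_plane(self) -> bool:
        return self.sign_vector[0] * self.sign_vector[1] == -1

    @property
    def reverses_orientation(self) -> bool:
        sx, sy, sz = self.sign_vector
        return sx * sy * sz == -1

    def __mul__(self, other: "SymmetryElement") -> "SymmetryElement":
        return compose_symmetry(self, other)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SymmetryElement({self.label})"


E = SymmetryElement("e", (1, 1, 1))
RX = SymmetryElement("rx", (1, -1, -1))
RY = SymmetryElement("ry", (-1, 1, -1))
RZ = SymmetryElement("rz", (-1, -1, 1))
MV = SymmetryElement("mv", (-1, 1, 1))  # reflection across the yz-plane
MH = SymmetryElement("mh", (1, -1, 1))  # reflection across the xz-plane
MSTAR = SymmetryElement("mstar", (1, 1, -1))  # mirror through the paper
INV = SymmetryElement("inv", (-1, -1, -1))

ELEMENTS: tuple[SymmetryElement, ...] = (E, RX, RY, RZ, MV, MH, MSTAR, INV)

_BY_VECTOR = {g.sign_vector: g for g in ELEMENTS}
_BY_LABEL = {g.label: g for g in ELEMENTS}


def element(label: str) -> SymmetryElement:
    """Look up a symmetry element by its label."""
    try:
        return _BY_LABEL[label]
    except KeyError:
        raise ValueError(f"unknown symmetry element {label!r}") from None


def compose_symmetry(a: SymmetryElement, b: SymmetryElement) -> SymmetryElement:
    """Group product a∘b via componentwise sign-vector multiplication.

    The group is abelian, every element is an involution, and composing two
    of the 180-degree rotations yields the third.
    """
    vec = tuple(x * y for x, y in zip(a.sign_vector, b.sign_vector))
    return _BY_VECTOR[vec]


def closure(gens: Iterable[SymmetryElement]) -> frozenset[SymmetryElement]:
    """Subgroup generated by ``gens`` (used for tile stabilizers)."""
    seen = {E}
    frontier = list(gens)
    while frontier:
        g = frontier.pop()
        if g not in seen:
            seen.add(g)
            frontier.extend(compose_symmetry(g, h) for h in list(seen))
    return frozenset(seen)
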