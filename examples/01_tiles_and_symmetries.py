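"""The sixteen allowed tiles and the rectangle symmetry group.

Soft contacts — locally entangled units of a polymer chain — are modelled
as rigid rectangular tiles.  Five base shapes exist; rotating and
reflecting them yields exactly sixteen distinct tiles, because many
transforms coincide (e.g. the in-plane rotation of the open trefoil tile
alpha is alpha itself, and its paper-plane mirror is alpha*).
"""

from collections import Counter

from tiletopo import apply_symmetry, enumerate_allowed_tiles, mirror, tile
from tiletopo.symmetry import ELEMENTS, RX, MSTAR

tiles = enumerate_allowed_tiles()
print(f"allowed tiles: {len(tiles)}")
by_family = Counter(t.family.name for t in tiles)
for fam, n in sorted(by_family.items()):
    members = sorted(t.canonical_label for t in tiles if t.family.name == fam)
    print(f"  {fam:8s} orbit of {n}: {', '.join(members)}")

print("\nsome identification relations:")
print("  delta rotated about its long axis:", apply_symmetry(tile("delta"), RX).canonical_label)
print("  delta mirrored through the paper: ", apply_symmetry(tile("delta"), MSTAR).canonical_label)
print("  epsilon under every rotation:     ",
      {apply_symmetry(tile("epsilon"), g).canonical_label for g in ELEMENTS if not g.reverses_orientation})
print("  mirror is an involution:", mirror(mirror(tile("gamma"))).canonical_label)

# Expected output: 16 tiles in orbits 4 (alpha), 4 (beta), 4 (delta),
# 2 (epsilon), 2 (gamma); delta_x = delta and delta^* = delta_h.
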