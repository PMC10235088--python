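# Methods

## The model

A *soft contact* is a locally entangled unit of a single polymer chain —
two segments twisted around each other and held by molecular forces, with
no covalent bond.  Because the entanglement is held in place, the unit is
treated as rigid: a rectangular *tile* carrying a fixed projection of a
1-string or 2-string tangle, with compass-labelled sides (short sides E
and W, long sides N and S) and, for 2-string tiles, one strand endpoint in
each corner.

Five base tiles generate everything:

| tile    | strings | shape                                   | crossings |
|---------|---------|-----------------------------------------|-----------|
| alpha   | 1       | open trefoil                            | 3         |
| beta    | 1       | open figure-eight                       | 4         |
| delta   | 2       | hook clasped through a loop             | 2         |
| epsilon | 2       | hook through a once-twisted loop        | 3         |
| gamma   | 2       | hook through a twice-twisted loop       | 4         |

The rectangle's rigid symmetries form the group (Z/2)^3: the identity,
the three 180-degree rotations r_x, r_y, r_z, the two in-plane mirrors,
the reflection through the plane of the paper (the `*`/mirror operation)
and the point inversion.  Each element is represented by its sign vector
on the coordinate axes, so composition is exact integer arithmetic.
Applying all eight elements to the five base tiles and identifying equal
results yields exactly sixteen distinct tiles, in orbits of sizes
4 (alpha), 4 (beta), 4 (delta), 2 (epsilon), 2 (gamma).  Each allowed
tile is stored as a coset of its family's stabilizer subgroup; the
symmetry action and all identification relations (alpha = alpha_z,
delta_h = delta^*, epsilon = epsilon_x = epsilon_y = epsilon_z, ...)
follow from the coset arithmetic and are property-tested over the whole
group.

Tile complexes are built by four operations: *closure* of a 2-string tile
(join its NE and NW endpoints), *cross* of two 2-string tiles (three
connector arcs; the traversal alternates A, B, A, B), *series*
(concatenation) and *parallel* (insertion of one complex into an interior
tile-free arc of another).  All crossings stay inside tiles; connector
arcs are planar and crossing-free.  *Sealing* joins the two free
endpoints — always possible without new crossings because they share a
region — and produces a knot.

## Notations and the conversion algorithm

Operation notation records construction; the ASCII grammar writes
`cl(A)`, `(A x B)`, `S + T`, `S ||_b T` with site suffixes `_t/_m/_b`
(cross arcs) and `_W/_E` (the two halves of an occupied arc).  Interior
arcs are addressed by paths into the expression tree, so insertion sites
are unambiguous; the two endpoint-bearing arcs are never insertable, and
insertion into a series connector is normalised to a new series summand
(the two describe the same picture).

Sequence notation records traversal: the letters of the tiles met from
the W endpoint to the E endpoint.  A sequence represents a complex
exactly when every letter appears once or twice and no letter alternates
with two others (X and Y alternate when their occurrences interleave
XYXY).  Conversion from a sequence runs the deletion/replay algorithm:
delete singletons, then repeatedly delete twins `XX` and adjacent
interweavings `XYXY` until empty — a valid singleton-free sequence always
contains one, which the suite property-tests on a thousand seeded
sequences — then rebuild in reverse, turning the last surviving blocks
into a series of closures and crosses and re-inserting each earlier
deletion at the unique arc between its recorded flanking traversal
positions (series when that arc is a connector between summands or an
endpoint, parallel otherwise; singletons re-enter last, left to right).
The rebuilt complex always traverses back to its input sequence, which is
asserted at run time.

Tile-complex equality is decided by canonicalization: two complexes are
equal when their traversal sequences rebuild the same expression with the
same letter-wise tile assignment.  The letter sequence is known to be
unique per complex; whether it is a *complete* invariant of planar
isotopy is not settled, so equality-as-implemented means "same canonical
form".  Every published example (the three equal notations of `ABBCCA`;
the unequal reassociated pair) is reproduced.

## The diagram engine

Each canonical tile has a crossing template: per strand, the ordered
crossing passages with the entry side and the over/under layer.  A
crossing is a 4-valent vertex with ports in counterclockwise order; this
rotation system fixes the embedding, and every sealed diagram is checked
against Euler's formula (V − E + F = 2 with F traced from the rotation
system), so a mis-transcribed template or impossible routing fails loudly
instead of silently producing a virtual diagram.  Transforming a template
by a symmetry renames corners, reverses the rotation order when the
in-plane part is a reflection, and swaps over/under when the projection
axis flips; knot handedness therefore flips exactly for the four
orientation-reversing isometries.

The drawings behind the templates come with one caveat.  The original
figure fixing the five projections was not available to this
implementation, so the templates are *reconstructions*: candidate shapes
(the hook-through-twisted-loop family above, plus open trefoil and
figure-eight braids) searched over their over/under patterns until one
assignment reproduced, simultaneously, all twelve rows of the published
cross-products table up to mirror, the nine mirror-completed pairs, and
the sealing classes of all basic complexes.  Exactly one assignment per
chirality convention survives, which is strong evidence the reconstructed
tangles are endpoint-fixing isotopic to the originals — and within this
package's scope (knot types of sealed complexes) the tangle class is all
that matters.  The gate is re-run by the test suite, so the fixture
cannot drift.

Sealed diagrams are oriented by traversal from the W endpoint, producing
PD codes (four incident arc labels counterclockwise from the incoming
under-strand), crossing signs (+1 when the over-strand enters at the
fourth position), the writhe, and signed Gauss codes.

## Invariants and identification

The Alexander polynomial is computed from the Wirtinger presentation via
Fox calculus: one relation row per crossing over the over-arc generators,
one column deleted, determinant taken.  The determinant is evaluated at
n + 1 integer points with fraction-free Bareiss elimination over Python
integers and recovered by exact Lagrange interpolation — exact arithmetic
without symbolic matrices.  Alexander polynomials are normalized to
minimum exponent 0 with positive lowest coefficient.

The Kauffman bracket is the literal 2^n state sum (loops counted by
union-find over the smoothing pairings), writhe-normalized and
re-expressed in the Jones variable.  The orientation of the smoothing
rule and the sign conventions are pinned by anchor diagrams: the
one-crossing kink must normalize to 1, the positive trefoil must give
−t^4 + t^3 + t, and the figure-eight must be palindromic.  The state sum
is capped (default 24 crossings) and raises a typed error beyond the cap.

Identification factors the Alexander polynomial over the ten-knot catalog
(3_1, 4_1, 5_1, 5_2, 6_1, 6_2, 6_3, 7_6, 7_7, 8_12) by exact polynomial
division with a bounded multiset search; the catalog polynomials are
pairwise distinct, and a trivial polynomial means the unknot (sound
within the reachable set, where no nontrivial knot has trivial
Alexander).  In the rare event of multiple factorizations the
lexicographically least multiset is returned.  Chirality is resolved by
matching the diagram's Jones polynomial against products of catalog Jones
values over sign assignments, collapsing assignments per catalog id (so a
square knot resolves to 3_1+ # 3_1− rather than two undetermined
trefoils); amphichiral factors (4_1, 6_3, 8_12) are marked `a`, and
factors the bracket cannot reach are left `?`.

Catalog reference diagrams are built at load time from rational (4-plat)
twist constructions; their invariants are computed by the engine itself
and validated against determinant checksums, never shipped as constants.

## The two knot-type routes

The symbolic route uses the connected-sum decomposition: series and
parallel composition both split the sealed knot into the connected sum of
the parts, so any expression folds down to its basic summands.  Sealings
of basic summands are computed once per engine from the templates:
1-string tiles seal to ±3_1 (alpha family) or 4_1 (beta family); sealed
closures give 0_1 (delta family), ±3_1 (epsilon) or 4_1 (gamma); crosses
are keyed by the unordered pair of endpoint-fixing tangle classes
{delta, delta*, epsilon, epsilon*, gamma, gamma*}.  The class of the
rotated tiles delta_y and delta_v is itself settled by the engine
(delta_y behaves as delta in every cross, delta_v as delta*) and frozen
in the tile algebra, where a test re-derives it.  Commutativity of the
cross in knot type is verified empirically, not assumed.

The diagram route never consults the decomposition, so agreement between
the two on random expressions is a genuine two-route check, which the
suite runs on 200 seeded expressions together with multiplicativity of
the Alexander polynomial over series and parallel combinations, and on
500 seeded expressions for closure of the reachable knot set.

## Random generators

Random expressions grow by seeded random application of the four
operations over uniformly chosen allowed tiles (a fresh `random.Random`
per call; identical configurations give identical output).  Defaults:
5 tiles, insertion depth at most 4, two-string probability 0.6 — enough
to exercise every operation and all sixteen tiles within a thousand
draws, while keeping sealed diagrams in the 4–24 crossing range where the
exact engines are fast.  Random sequences are traversals of random
expressions, which samples exactly the language of valid sequences since
every valid sequence is the traversal of its canonical complex.  These
generators emulate the combinatorial space of the model itself, not any
empirical distribution of entanglements in real proteins; passing tests
certify the algebra and the engines, and say nothing about how often a
given motif occurs in nature.

## Problem sizes and numerical choices

The suite's heavy properties use 2–6 tiles per expression (diagrams up to
24 crossings).  Alexander identification is exact at every size used;
Jones-based chirality is computed when a diagram has at most 14 crossings
in the batch tests (the per-engine cap stays 24), and the closure
property of the reachable set runs Alexander-only, since chirality plays
no role there.  Degenerate inputs are handled explicitly: the empty
sequence has no complex (rejected), one- and two-crossing diagrams
normalize to the unknot, crossingless welds (which would create a free
loop) raise, and multi-component traversals are rejected before any
invariant is computed.

## Known limitations

* Hard contacts (covalent intra-chain bonds), multi-chain systems and
  stacked crosses are out of scope.
* Equality of complexes is decided through sequence canonicalization;
  completeness of that invariant is unproven (no counterexample is
  known, and all published examples agree).
* Unknot detection by trivial Alexander polynomial is sound only within
  the reachable knot set — by the classification this is every sealed
  tile complex, and the engine raises if a diagram's invariants ever
  leave the catalog.
* Chirality of a factor is undetermined when the Jones state sum is out
  of reach and the Jones product is ambiguous; the prime decomposition
  itself is unaffected.
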