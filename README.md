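# tiletopo

Circuit-topology tile model for self-entangled biopolymers.

Knotted proteins and other self-entangled polymer chains carry *soft
contacts*: locally entangled units held together by molecular forces
rather than covalent bonds.  `tiletopo` models each soft contact as a
rigid rectangular **tile** — a fixed projection of a 1-string or 2-string
tangle — and an entangled chain as a **tile complex** built from tiles by
four operations:

* closure `cl(A)` — join the NE and NW endpoints of a 2-string tile;
* cross `(A x B)` — join two 2-string tiles so the strand alternates
  A, B, A, B;
* series `S + T` — concatenate two complexes;
* parallel `S ||_p T` — insert a complex into an interior arc of another.

Five base tiles (an open trefoil `alpha`, an open figure-eight `beta`,
and a hook clasped through a loop with 0, 1 or 2 extra twists: `delta`,
`epsilon`, `gamma`) generate, under the rectangle's rotations and
reflections, exactly **16 allowed tiles**.  *Sealing* a complex — joining
its two free endpoints with a crossing-free planar arc — produces a knot
K(S), and the central classification the package reproduces is:

> the sealing of every tile complex is a connected sum of knots from
> {3₁, 4₁, 5₁, 5₂, 6₁, 6₂, 6₃, 7₆, 7₇, 8₁₂} and their mirror images —
> which covers every protein knot identified so far.

The package computes K(S) two independent ways: **symbolically** (the
connected-sum decomposition into basic summands, with crosses looked up
by the endpoint-fixing tangle classes δ, δ\*, ε, ε\*, γ, γ\*) and **from
planar diagrams** (explicit PD codes assembled from per-tile crossing
templates, identified by Alexander and Jones polynomials).  It also
implements both notations for complexes — operation notation and the
traversal *sequence notation* — with validation and the conversion
algorithm between them.

For whom: researchers in structural bioinformatics and applied knot
theory who want to enumerate, name, compare, and classify soft-contact
entanglements, and anyone needing a small exact engine for knot
invariants of combinatorially described diagrams.

## A worked example

The sequence read along a chain with ten tile passages:

```python
>>> from tiletopo import Sequence, sequence_to_expression, format_operation_notation
>>> expr = sequence_to_expression(Sequence.from_string("ABADDEBCFC"))
>>> format_operation_notation(expr)
'((A x B) ||_b (cl(D) + E)) + (cl(C) || F)'
```

i.e. the chain is a cross of A and B with a closed D and a 1-string E
inserted into its bottom arc, followed in series by a closed C carrying a
1-string F.  Assign tiles and seal:

```python
>>> from tiletopo import default_engine, parse_operation_notation
>>> engine = default_engine()
>>> e = parse_operation_notation("(A=delta x B=delta)")
>>> str(engine.knot_type_symbolic(e))
'3_1+'
>>> d = engine.build(e)                      # explicit planar diagram
>>> d.n_crossings, str(engine.identify_knot(d))
(4, '3_1+')
>>> str(engine.knot_type_symbolic(parse_operation_notation(
...     "cl(A=epsilon) || cl(B=epsilon*)")))
'3_1+ # 3_1-'
```

The cross of two clasp tiles seals to a positive trefoil by both engines;
a parallel pair of mirror-image twisted-loop closures gives the square
knot.  The published cross-products table rebuilds from the templates row
by row:

```bash
$ tiletopo verify-table1
ok   K(delta x delta) = 3_1+ (table: 3_1)
ok   K(delta* x delta) = 4_1a (table: 4_1)
...          # 12 printed rows + 9 mirror-completed pairs
all rows verified
```

The same functionality is scriptable from the shell: `tiletopo validate`,
`seq2op`, `op2seq`, `knottype`, `verify-table1`, `generate`, `selftest`.
The `examples/` directory holds short narrative scripts, one per
capability, with the numbers they print explained inline.

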