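"""Knot types of sealed tile complexes, two ways.

Sealing joins the free endpoints of a complex with a crossing-free planar
arc, producing a knot.  The symbolic engine decomposes the complex into
basic summands and looks their sealings up (connected-sum decomposition);
the diagram engine builds the explicit planar diagram and identifies it by
Alexander and Jones polynomials.  They must agree.
"""

from tiletopo import alexander_polynomial, default_engine, parse_operation_notation

engine = default_engine()

examples = [
    "(A=delta x B=delta)",          # the simplest knotted cross: a trefoil
    "(A=gamma* x B=gamma)",         # the largest prime reachable: 8_12
    "cl(A=epsilon) + B=alpha",      # a connected sum via series
    "cl(A=epsilon) || cl(B=epsilon*)",  # parallel also sums: the square knot
]
for text in examples:
    expr = parse_operation_notation(text)
    symbolic = engine.knot_type_symbolic(expr)
    diagram = engine.build(expr)
    identified = engine.identify_knot(diagram)
    alex = alexander_polynomial(diagram)
    print(f"{text:34s} symbolic {str(symbolic):14s} diagram {str(identified):14s}"
          f" n={diagram.n_crossings} Alexander: {alex}")

# Expected output: 3_1, 8_12a, 3_1 # 3_1 (same chirality), 3_1+ # 3_1-;
# both engines printing the same prime decomposition, with the Alexander
# polynomial multiplying over connected summands.
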