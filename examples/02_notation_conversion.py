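"""Converting between sequence and operation notation.

A tile complex read along its oriented arc gives a letter sequence; the
reverse direction (sequence -> one operation notation) runs the deletion/
replay algorithm: strip singletons, repeatedly delete twins (XX) and
interweavings (XYXY), then rebuild with series and parallel insertions.
"""

from tiletopo import (
    Sequence,
    format_operation_notation,
    parse_operation_notation,
    sequence_to_expression,
    to_sequence,
    validate_sequence,
)

# the worked example: a 10-letter sequence with two singletons
seq = Sequence.from_string("ABADDEBCFC")
print("sequence:", seq, "valid:", validate_sequence(seq) == [])
expr = sequence_to_expression(seq)
print("operation notation:", format_operation_notation(expr))
print("read back:", to_sequence(expr))

# an invalid sequence: D alternates with both A and B, which no planar
# tile complex can realize
bad = Sequence.from_string("ABDBAD")
for violation in validate_sequence(bad):
    print("rejected:", violation)

# different constructions can give the same complex; canonicalization
# through the sequence recovers one notation for all of them
for text in ("(cl(A) || cl(C)) ||_W cl(B)", "cl(A) || (cl(B) + cl(C))"):
    e = parse_operation_notation(text)
    canon = sequence_to_expression(to_sequence(e))
    print(f"{text:32s} -> {format_operation_notation(canon)}")

# Expected output: ABADDEBCFC <-> ((A x B) ||_b (cl(D) + E)) + (cl(C) || F);
# ABDBAD rejected under Requirement 2; both notations canonicalize to
# cl(A) || (cl(B) + cl(C)).
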