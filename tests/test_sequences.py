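"""Sequence notation: validity requirements, reduction, and the
sequence-to-operation-notation algorithm."""

import pytest
from hypothesis import given, settings, strategies as st

from tiletopo.expressions import insert, list_insertable_arcs
from tiletopo.generators import GeneratorConfig, random_expression, random_valid_sequence
from tiletopo.grammar import format_operation_notation, parse_operation_notation
from tiletopo.sequences import (
    Sequence,
    complexes_equal,
    find_singletons,
    find_twins_and_interweavings,
    reduce_once,
    sequence_to_expression,
    to_sequence,
    validate_sequence,
)
from tiletopo.tiles import tile


S = Sequence.from_string


# -- validity ---------------------------------------------------------------


def test_worked_example_sequence_is_valid():
    assert validate_sequence(S("ABADDEBCFC")) == []


def test_three_way_alternation_violates_requirement_two():
    violations = validate_sequence(S("ABDBAD"))
    assert len(violations) == 1
    assert "Requirement 2" in violations[0]
    assert "D" in violations[0] and "A" in violations[0] and "B" in violations[0]


def test_empty_sequence_is_vacuously_valid():
    assert validate_sequence(S("")) == []


def test_letter_thrice_violates_requirement_one():
    assert any("Requirement 1" in v for v in validate_sequence(S("AAA")))


def test_arity_mismatched_assignment_is_reported():
    bad = Sequence.from_string("AA", {"A": tile("alpha")})
    assert any("1-string" in v for v in validate_sequence(bad))
    good = Sequence.from_string("AA", {"A": tile("delta")})
    assert validate_sequence(good) == []


# -- singletons, twins, interweavings --------------------------------------


def test_singletons_of_the_worked_example():
    assert find_singletons(S("ABADDEBCFC")) == {"E", "F"}
    assert find_singletons(S("AABB")) == set()
    assert find_singletons(S("Q")) == {"Q"}


def test_twins_found_with_positions():
    blocks = find_twins_and_interweavings(S("ABADDBCC"))
    assert [(b.kind, b.letters, b.start) for b in blocks] == [
        ("twins", ("D",), 3),
        ("twins", ("C",), 6),
    ]


def test_interweaving_found():
    blocks = find_twins_and_interweavings(S("ABAB"))
    assert [(b.kind, b.letters) for b in blocks] == [("interweaving", ("A", "B"))]


def test_non_adjacent_alternation_is_not_an_interweaving():
    # A and B alternate in ABACCB but the interweaving is not adjacent
    blocks = find_twins_and_interweavings(S("ABACCB"))
    assert [(b.kind, b.letters) for b in blocks] == [("twins", ("C",))]


# -- reduction --------------------------------------------------------------


def test_reduce_once_deletes_all_blocks_of_the_scan():
    reduced, blocks = reduce_once(S("ABADDBCC"))
    assert str(reduced) == "ABAB"
    assert len(blocks) == 2


def test_reduction_reaches_empty_for_the_worked_example():
    reduced, _ = reduce_once(S("ABAB"))
    assert str(reduced) == ""
    reduced, _ = reduce_once(S("AA"))
    assert str(reduced) == ""


# -- the algorithm ----------------------------------------------------------


def test_worked_example_rebuilds_the_published_notation():
    e = sequence_to_expression(S("ABADDEBCFC"))
    assert format_operation_notation(e) == "((A x B) ||_b (cl(D) + E)) + (cl(C) || F)"


def test_abbcca_rebuilds_the_single_canonical_notation():
    e = sequence_to_expression(S("ABBCCA"))
    assert format_operation_notation(e) == "cl(A) || (cl(B) + cl(C))"


def test_twins_alone_rebuild_a_closure():
    assert format_operation_notation(sequence_to_expression(S("AA"))) == "cl(A)"


def test_all_singletons_rebuild_a_series():
    assert format_operation_notation(sequence_to_expression(S("ABC"))) == "A + B + C"


def test_invalid_sequence_is_rejected():
    with pytest.raises(ValueError):
        sequence_to_expression(S("ABDBAD"))


def test_empty_sequence_has_no_complex():
    with pytest.raises(ValueError):
        sequence_to_expression(S(""))


# -- tile-complex equality --------------------------------------------------


def test_three_notations_of_the_same_complex_are_equal():
    a = parse_operation_notation("(cl(A) || cl(C)) ||_W cl(B)")
    b = parse_operation_notation("(cl(A) || cl(B)) ||_E cl(C)")
    c = parse_operation_notation("cl(A) || (cl(B) + cl(C))")
    assert to_sequence(a).letters == tuple("ABBCCA")
    assert complexes_equal(a, b) and complexes_equal(b, c) and complexes_equal(a, c)


def test_reassociated_parallel_is_a_different_complex():
    d1 = parse_operation_notation("(cl(A) || cl(B)) ||_W cl(C)")
    d2 = parse_operation_notation("cl(A) || (cl(B) || cl(C))")
    assert not complexes_equal(d1, d2)


def test_equality_is_reflexive_on_random_expressions():
    for seed in range(10):
        e = random_expression(GeneratorConfig(n_tiles=4, seed=seed))
        assert complexes_equal(e, e)


# -- properties -------------------------------------------------------------


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 100_000), st.integers(1, 9))
def test_algorithm_round_trips_every_valid_sequence(seed, n_tiles):
    seq = random_valid_sequence(GeneratorConfig(n_tiles=n_tiles, seed=seed))
    assert validate_sequence(seq) == []
    rebuilt = sequence_to_expression(seq)
    assert to_sequence(rebuilt).letters == seq.letters


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 100_000), st.integers(2, 9))
def test_nonempty_singleton_free_sequences_always_reduce(seed, n_tiles):
    seq = random_valid_sequence(GeneratorConfig(n_tiles=n_tiles, seed=seed))
    singles = find_singletons(seq)
    letters = tuple(ch for ch in seq.letters if ch not in singles)
    current = Sequence(letters)
    while len(current):
        assert find_twins_and_interweavings(current), str(current)
        shorter, _ = reduce_once(current)
        assert len(shorter) < len(current)
        current = shorter


def test_insertion_into_a_series_connector_becomes_a_summand():
    host = parse_operation_notation("cl(A) + cl(B)")
    piece = parse_operation_notation("cl(C)")
    combined = insert(host, piece, ("conn",))
    assert format_operation_notation(combined) == "cl(A) + cl(C) + cl(B)"
    assert ("conn",) in list_insertable_arcs(host)
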