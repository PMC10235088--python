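"""The sixteen allowed tiles and the symmetry action on them."""

import itertools
from collections import Counter

import pytest

from tiletopo.symmetry import ELEMENTS, MSTAR, RX, RY, RZ, MV, MH, INV, E, compose_symmetry
from tiletopo.tiles import (
    ALL_TILES,
    apply_symmetry,
    enumerate_allowed_tiles,
    mirror,
    mirror_class,
    tangle_class,
    tile,
)


def test_census_sixteen_tiles_in_family_orbits_4_4_4_2_2():
    tiles = enumerate_allowed_tiles()
    assert len(tiles) == 16
    sizes = Counter(t.family.name for t in tiles)
    assert sizes == {"alpha": 4, "beta": 4, "delta": 4, "epsilon": 2, "gamma": 2}


def test_arities():
    for t in ALL_TILES:
        assert t.arity == (1 if t.family.name in ("alpha", "beta") else 2)


@pytest.mark.parametrize(
    "label, g, expected",
    [
        # alpha family: alpha = alpha_z, alpha* = alpha_z*, alpha_v = alpha_h,
        # alpha_x = alpha_y
        ("alpha", RZ, "alpha"),
        ("alpha", MSTAR, "alpha*"),
        ("alpha", MV, "alpha_v"),
        ("alpha", MH, "alpha_v"),
        ("alpha", RX, "alpha_x"),
        ("alpha", RY, "alpha_x"),
        ("alpha", INV, "alpha*"),
        # beta family: beta = beta_z*, beta_z = beta*, beta_v = beta_x,
        # beta_h = beta_y
        ("beta", INV, "beta"),
        ("beta", RZ, "beta_z"),
        ("beta", MSTAR, "beta_z"),
        ("beta", MV, "beta_v"),
        ("beta", RX, "beta_v"),
        ("beta", MH, "beta_h"),
        ("beta", RY, "beta_h"),
        # delta family: delta = delta_x, delta_y = delta_z, delta_h = delta*,
        # delta_v = delta_z*
        ("delta", RX, "delta"),
        ("delta", RY, "delta_y"),
        ("delta", RZ, "delta_y"),
        ("delta", MH, "delta_h"),
        ("delta", MSTAR, "delta_h"),
        ("delta", MV, "delta_v"),
        ("delta", INV, "delta_v"),
        # epsilon and gamma: all rotations fix them, all reflections star them
        ("epsilon", RX, "epsilon"),
        ("epsilon", RY, "epsilon"),
        ("epsilon", RZ, "epsilon"),
        ("epsilon", MV, "epsilon*"),
        ("epsilon", MH, "epsilon*"),
        ("epsilon", MSTAR, "epsilon*"),
        ("epsilon", INV, "epsilon*"),
        ("gamma", RZ, "gamma"),
        ("gamma", MV, "gamma*"),
    ],
)
def test_identification_relations(label, g, expected):
    assert apply_symmetry(tile(label), g) == tile(expected)


def test_apply_symmetry_is_a_group_action():
    for t in ALL_TILES:
        assert apply_symmetry(t, E) == t
        for g, h in itertools.product(ELEMENTS, repeat=2):
            assert apply_symmetry(apply_symmetry(t, g), h) == apply_symmetry(
                t, compose_symmetry(h, g)
            )


def test_orbits_partition_each_family():
    for base in ("alpha", "beta", "delta", "epsilon", "gamma"):
        orbit = {apply_symmetry(tile(base), g) for g in ELEMENTS}
        family_tiles = {t for t in ALL_TILES if t.family.name == base}
        assert orbit == family_tiles


def test_mirror_is_an_involution_and_matches_star_labels():
    for t in ALL_TILES:
        assert mirror(mirror(t)) == t
    assert mirror(tile("delta")) == tile("delta_h")
    assert mirror(tile("epsilon")) == tile("epsilon*")
    assert mirror(tile("alpha")) == tile("alpha*")


def test_corner_pairing_is_a_perfect_matching_of_the_corners():
    for t in ALL_TILES:
        if t.arity != 2:
            with pytest.raises(ValueError):
                t.corner_pairing
            continue
        pairing = t.corner_pairing
        corners = {c for pair in pairing for c in pair}
        assert corners == {"NE", "NW", "SW", "SE"}
        assert all(len(pair) == 2 for pair in pairing)


def test_tangle_class_maps_onto_the_six_classes():
    classes = {tangle_class(t) for t in ALL_TILES if t.arity == 2}
    assert classes == {
        "delta", "delta*", "epsilon", "epsilon*", "gamma", "gamma*"
    }


def test_tangle_class_commutes_with_mirror():
    for t in ALL_TILES:
        if t.arity == 2:
            assert tangle_class(mirror(t)) == mirror_class(tangle_class(t))


def test_tangle_class_rejects_one_string_tiles():
    with pytest.raises(ValueError):
        tangle_class(tile("alpha"))


def test_delta_rotations_split_between_the_two_classes():
    # delta_h is the paper-plane mirror of delta, hence class delta*; the
    # rotated tiles fill in so the class map stays mirror-consistent
    assert tangle_class(tile("delta")) == "delta"
    assert tangle_class(tile("delta_h")) == "delta*"
    assert {tangle_class(tile("delta_y")), tangle_class(tile("delta_v"))} == {
        "delta", "delta*"
    }


def test_unknown_label_rejected():
    with pytest.raises(ValueError):
        tile("delta_q")
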