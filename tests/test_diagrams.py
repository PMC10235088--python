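"""The planar diagram engine: templates, sealing, traversal, exports."""

import re

import pytest

from tiletopo.constructions import braid_closure
from tiletopo.diagrams import TraversalError, build_sealed_diagram, writhe
from tiletopo.expressions import Closure, Cross, Leaf1, Series
from tiletopo.grammar import parse_operation_notation
from tiletopo.symmetry import ELEMENTS, E, MSTAR, RX, RY, RZ, compose_symmetry
from tiletopo.templates import (
    TemplateError,
    _template_from_spec,
    load_base_templates,
    load_tile_templates,
    transform_template,
)
from tiletopo.tiles import ALL_TILES, tile


@pytest.fixture(scope="module")
def templates():
    return load_tile_templates()


TEMPLATE_CROSSINGS = {"alpha": 3, "beta": 4, "delta": 2, "epsilon": 3, "gamma": 4}


def test_all_five_base_templates_load(templates):
    base = load_base_templates()
    assert set(base) == {"alpha", "beta", "delta", "epsilon", "gamma"}
    for name, tpl in base.items():
        assert tpl.n_crossings == TEMPLATE_CROSSINGS[name]


def test_all_sixteen_tiles_have_templates(templates):
    assert set(templates) == {t.canonical_label for t in ALL_TILES}


def test_malformed_fixture_is_diagnosed():
    with pytest.raises(TemplateError, match="perpendicular"):
        _template_from_spec(
            "bad",
            {
                "arity": 2,
                "strands": {
                    "west": [["c1", "S", "o"], ["c2", "S", "u"]],
                    "east": [["c1", "N", "u"], ["c2", "W", "o"]],
                },
            },
        )
    with pytest.raises(TemplateError, match="over and one under"):
        _template_from_spec(
            "bad",
            {
                "arity": 2,
                "strands": {
                    "west": [["c1", "S", "o"], ["c2", "S", "u"]],
                    "east": [["c1", "E", "o"], ["c2", "W", "o"]],
                },
            },
        )


def test_crossing_count_is_the_sum_over_tiles(templates):
    # connector and sealing arcs contribute no crossings
    for label, n in (("delta", 2), ("epsilon", 3), ("gamma", 4)):
        d = build_sealed_diagram(Closure("A", tile(label)), templates)
        assert d.n_crossings == n
    d = build_sealed_diagram(
        Cross("A", "B", tile("delta"), tile("gamma")), templates
    )
    assert d.n_crossings == 6
    e = parse_operation_notation("cl(A=epsilon) + (B=delta x C=delta)")
    assert build_sealed_diagram(e, templates).n_crossings == 7


def test_sealed_diagram_is_one_closed_component(templates):
    # the traversal closes after exactly 2n edges; _orient enforces it
    for label in ("alpha", "beta"):
        d = build_sealed_diagram(Leaf1("A", tile(label)), templates)
        assert len(d.crossings) == TEMPLATE_CROSSINGS[label]


def test_cross_traversal_alternates_between_the_two_tiles(templates):
    d = build_sealed_diagram(
        Cross("A", "B", tile("delta"), tile("delta_y")), templates
    )
    # compress the per-passage tile labels of the oriented traversal
    passages = []
    for c in sorted(
        (arc, cr.label) for cr in d.crossings for arc in _entry_arcs(cr)
    ):
        if not passages or passages[-1] != c[1]:
            passages.append(c[1])
    assert passages == ["A", "B", "A", "B"]


def _entry_arcs(pdc):
    a = pdc.arcs[0]
    over_in = pdc.arcs[3] if pdc.sign > 0 else pdc.arcs[1]
    return (a, over_in)


def test_closure_traversal_passes_its_tile_twice(templates):
    for label in ("delta", "epsilon", "gamma", "delta_h"):
        d = build_sealed_diagram(Closure("A", tile(label)), templates)
        labels = {c.label for c in d.crossings}
        assert labels == {"A"}


def test_writhe_flips_under_mirror_and_adds_under_series(templates):
    e1 = Leaf1("A", tile("alpha"))
    e2 = Leaf1("A", tile("alpha*"))
    d1 = build_sealed_diagram(e1, templates)
    d2 = build_sealed_diagram(e2, templates)
    assert writhe(d1) == -writhe(d2) != 0
    assert writhe(d1.mirror()) == -writhe(d1)
    both = build_sealed_diagram(
        Series(Leaf1("A", tile("alpha")), Leaf1("B", tile("alpha"))), templates
    )
    assert writhe(both) == 2 * writhe(d1)


def test_pd_code_and_gauss_code_formats():
    d = braid_closure([1, 1, 1])
    assert re.fullmatch(r"(X\[\d+,\d+,\d+,\d+\] ?){3}", d.pd_code())
    gauss = d.gauss_code().split()
    assert len(gauss) == 6
    assert {tok[0] for tok in gauss} == {"O", "U"}
    # each crossing appears once as O and once as U
    nums = [tok[1:-1] for tok in gauss]
    assert sorted(nums) == ["1", "1", "2", "2", "3", "3"]


def test_transform_template_composes_like_the_group(templates):
    base = load_base_templates()["gamma"]
    for g, h in ((RX, RY), (RY, RZ), (MSTAR, RX)):
        once = transform_template(transform_template(base, g), h)
        joint = transform_template(base, compose_symmetry(h, g))
        assert once.over_02 == joint.over_02
        assert once.links == joint.links


def test_mirror_transform_fixes_endpoints_and_flips_layers(templates):
    base = load_base_templates()["delta"]
    mirrored = transform_template(base, MSTAR)
    assert mirrored.over_02 == [not o for o in base.over_02]
    assert set(mirrored.ends()) == set(base.ends())
    assert transform_template(transform_template(base, MSTAR), MSTAR).links == base.links


def test_identity_transform_is_identity(templates):
    base = load_base_templates()["epsilon"]
    same = transform_template(base, E)
    assert same.links == base.links and same.over_02 == base.over_02


def test_nonplanar_routing_is_rejected():
    # a rotation system whose faces close up only on a torus: a clasp whose
    # west strand also self-crosses in a way no drawing can realize
    spec = {
        "arity": 2,
        "strands": {
            "west": [
                ["cT", "W", "o"],
                ["c1", "S", "o"],
                ["c2", "S", "u"],
                ["cT", "N", "u"],
            ],
            "east": [["c1", "E", "u"], ["c2", "W", "o"]],
        },
    }
    bad = _template_from_spec("bad", spec)
    templates = {"epsilon": bad}
    with pytest.raises(TraversalError, match="not planar"):
        build_sealed_diagram(Closure("A", tile("epsilon")), templates)


def test_missing_tile_assignment_is_an_error(templates):
    with pytest.raises(ValueError, match="no tile assigned"):
        build_sealed_diagram(Closure("A"), templates)
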