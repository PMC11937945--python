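"""Building-block extraction, taxonomy, and defining-block assignment."""

import pytest

from fibersym import (
    DirectedMultigraph,
    assign_defining_blocks,
    classify_block,
    extract_block,
    fibonacci_conditions,
    find_fibers,
)
from fibersym.building_blocks import (
    FAMILY_COMPOSITE_FB,
    FAMILY_COMPOSITE_FF,
    FAMILY_FIBONACCI,
    FAMILY_MULTILAYER,
    FAMILY_NL,
)
from fibersym.network_builder import make_complexity_ladder

GOLDEN = (1 + 5**0.5) / 2


def lifted_simple_fibonacci():
    """Two-member fiber with a self-loop source, feedback 2-cycle with one regulator."""
    return DirectedMultigraph.from_edges(
        [("F1", "F1"), ("F1", "F2"), ("R", "F1"), ("R", "F2"), ("F1", "R")]
    )


def block_of(g, member, **kwargs):
    p = find_fibers(g)
    b = extract_block(g, p, member)
    return b, classify_block(b, p, **kwargs), p


class TestExtractBlock:
    def test_simple_fibonacci_members_and_ratio(self):
        g = lifted_simple_fibonacci()
        b, _, _ = block_of(g, "F1")
        assert b.focal_fiber == frozenset({"F1", "F2"})
        assert b.regulators == frozenset({"R"})
        assert b.members == frozenset({"F1", "F2", "R"})
        assert b.branching.value == pytest.approx(GOLDEN, abs=1e-6)

    def test_feedforward_block_excludes_regulator_upstream(self):
        # two distinguishable regulators fed by an upstream source pool
        g = DirectedMultigraph.from_edges(
            [
                ("S1", "R1"),
                ("S1", "R2"), ("S2", "R2"),
                ("R1", "F1"), ("R1", "F2"),
                ("R2", "F1"), ("R2", "F2"),
            ]
        )
        b, cls, _ = block_of(g, "F1")
        assert b.members == frozenset({"F1", "F2", "R1", "R2"})
        assert b.branching.status == "finite_tree"
        assert cls.family == FAMILY_NL and (cls.n, cls.l) == (0, 2)

    def test_shortest_feedback_path_intermediate_included(self):
        # feedback from fiber to regulator passes through intermediate node I
        g = DirectedMultigraph.from_edges(
            [
                ("F1", "F1"), ("F1", "F2"),
                ("R", "F1"), ("R", "F2"),
                ("F1", "I"), ("I", "R"),
            ]
        )
        b, _, _ = block_of(g, "F1")
        assert "I" in b.members

    def test_all_tied_shortest_paths_included(self):
        g = DirectedMultigraph.from_edges(
            [
                ("F1", "F1"), ("F1", "F2"),
                ("R", "F1"), ("R", "F2"),
                ("F1", "I1"), ("I1", "R"),
                ("F1", "I2"), ("I2", "R"),
                ("F1", "J1"), ("J1", "J2"), ("J2", "R"),  # longer path: excluded
            ]
        )
        b, _, _ = block_of(g, "F1")
        assert {"I1", "I2"} <= b.members
        assert not {"J1", "J2"} & b.members

    def test_unknown_fiber_id(self):
        g = lifted_simple_fibonacci()
        p = find_fibers(g)
        with pytest.raises(KeyError):
            extract_block(g, p, "nope")
        with pytest.raises(KeyError):
            extract_block(g, p, 99)


class TestClassification:
    def test_complexity_ladder_families_and_ratios(self):
        expected = [
            (FAMILY_NL, 1.0),
            (FAMILY_NL, 1.0),
            (FAMILY_FIBONACCI, GOLDEN),
            (FAMILY_COMPOSITE_FF, GOLDEN),
            (FAMILY_COMPOSITE_FB, 2.0),
        ]
        steps = make_complexity_ladder()
        for (g, focal), (family, r) in zip(steps, expected):
            b, cls, _ = block_of(g, focal)
            assert cls.family == family
            assert b.branching.value == pytest.approx(r, abs=1e-6)
        # |n,l> labels of the first two steps
        _, c0, _ = block_of(steps[0][0], steps[0][1])
        _, c1, _ = block_of(steps[1][0], steps[1][1])
        assert (c0.n, c0.l) == (1, 0)
        assert (c1.n, c1.l) == (1, 1)

    def test_feedforward_composite_inherits_regulator_ratio(self):
        g, focal = make_complexity_ladder()[3]
        b, cls, p = block_of(g, focal)
        reg_b = extract_block(g, p, "F1")
        assert b.branching.value == pytest.approx(reg_b.branching.value, abs=1e-6)

    def test_multilayer_composed_label(self):
        g = DirectedMultigraph.from_edges(
            [
                ("h", "Y1"), ("h", "Y2"),
                ("h", "X1"), ("h", "X2"),
                ("Y1", "X1"), ("Y2", "X2"),
            ]
        )
        b, cls, _ = block_of(g, "X1")
        assert cls.family == FAMILY_MULTILAYER
        assert cls.label == "|0,3>(+)|0,1>"
        assert b.branching.value == 0.0

    def test_stable_under_node_relabeling(self):
        g = lifted_simple_fibonacci()
        relabeled = DirectedMultigraph.from_edges(
            [("zz1", "zz1"), ("zz1", "qq"), ("aa", "zz1"), ("aa", "qq"), ("zz1", "aa")]
        )
        _, c1, _ = block_of(g, "F1")
        _, c2, _ = block_of(relabeled, "zz1")
        assert (c1.family, round(c1.r, 9)) == (c2.family, round(c2.r, 9))


class TestFibonacciConditions:
    def test_simple_fibonacci_both_conditions(self):
        g = lifted_simple_fibonacci()
        p = find_fibers(g)
        b = extract_block(g, p, "F1")
        assert fibonacci_conditions(b) == (True, True)

    def test_chain_block_self_loop_only(self):
        g, focal = make_complexity_ladder()[1]  # |1,1>
        p = find_fibers(g)
        b = extract_block(g, p, focal)
        assert fibonacci_conditions(b) == (False, True)
        assert b.branching.value == pytest.approx(1.0)

    def test_feedforward_block_neither(self):
        g = DirectedMultigraph.from_edges(
            [("S1", "R1"), ("S1", "R2"), ("S2", "R2"),
             ("R1", "F1"), ("R1", "F2"), ("R2", "F1"), ("R2", "F2")]
        )
        p = find_fibers(g)
        b = extract_block(g, p, "F1")
        assert fibonacci_conditions(b) == (False, False)
        assert b.branching.value == 0.0


class TestDefiningBlocks:
    def test_nested_blocks_smallest_defines(self):
        # simple Fibonacci fiber {F1,F2}; second fiber {Y1,Y2} regulated by it
        # closes a longer 3-cycle F -> Y -> R -> F
        g = DirectedMultigraph.from_edges(
            [
                ("F1", "F1"), ("F1", "F2"),
                ("R", "F1"), ("R", "F2"),
                ("F1", "R"),
                ("F1", "Y1", "m2"), ("F1", "Y2", "m2"),
                ("Y1", "R"), ("Y2", "R"),
            ]
        )
        p = find_fibers(g)
        f_fiber = p.fiber_of("F1")
        y_fiber = p.fiber_of("Y1")
        assert f_fiber == frozenset({"F1", "F2"}) and y_fiber == frozenset({"Y1", "Y2"})
        blocks = [extract_block(g, p, "F1"), extract_block(g, p, "Y1")]
        # the first fiber's block ignores the longer cycle through Y
        assert blocks[0].members == frozenset({"F1", "F2", "R"})
        # the second fiber's block stitches in the Fibonacci fiber, and the cycle
        assert blocks[1].members == frozenset({"F1", "F2", "R", "Y1", "Y2"})
        defining = assign_defining_blocks(blocks)
        assert defining[f_fiber] is blocks[0]
        assert defining[y_fiber] is blocks[1]

    def test_single_block_defines_itself(self):
        g = lifted_simple_fibonacci()
        p = find_fibers(g)
        b = extract_block(g, p, "F1")
        assert assign_defining_blocks([b])[b.focal_fiber] is b

    def test_total_and_single_valued(self):
        steps = make_complexity_ladder()
        g, _ = steps[4]
        p = find_fibers(g)
        blocks = [
            extract_block(g, p, i)
            for i in range(len(p.fibers))
            if len(p.fibers[i]) >= 2
        ]
        defining = assign_defining_blocks(blocks)
        for blk in blocks:
            assert blk.focal_fiber in defining
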