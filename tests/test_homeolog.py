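"""Homeolog grouping, typing, nomenclature, and catalog statistics."""
from __future__ import annotations

import pytest

from familymap.homeolog import (
    HomeologError,
    assign_names,
    fold_ratio,
    infer_groups,
    round_pct,
    summary_stats,
    type_groups,
)
from familymap.phylo import TreeNode

from conftest import make_record


def leaf(name):
    return TreeNode(label=name, length=0.1)


def node(*children):
    return TreeNode(children=list(children), length=0.1)


def test_triad_clade_becomes_one_group():
    recs = [
        make_record("xA", "A", 4, 100),
        make_record("xB", "B", 4, 100),
        make_record("xD", "D", 4, 100),
        make_record("y", "D", 1, 50),
    ]
    tree = TreeNode(children=[
        node(node(leaf("xA.1"), leaf("xB.1")), leaf("xD.1")),
        leaf("y.1"),
    ])
    groups = infer_groups(tree, recs)
    by_type = {g.homeolog_type: g for g in groups}
    assert set(by_type) == {"A:B:D", "D"}
    assert {m.gene_id for m in by_type["A:B:D"].members} == {"xA", "xB", "xD"}
    assert by_type["D"].complement == 1


def test_duplicate_subgenome_blocks_merging():
    recs = [make_record("x1", "A", 4, 10), make_record("x2", "A", 4, 20)]
    tree = TreeNode(children=[leaf("x1.1"), leaf("x2.1"),
                              TreeNode(label="z.1", length=0.5)])
    recs.append(make_record("z", "B", 2, 5))
    groups = infer_groups(tree, recs)
    assert len(groups) == 3
    assert all(len(g.members) == 1 for g in groups)


def test_mixed_complement_clade_is_split():
    recs = [make_record("a", "A", 1, 10), make_record("b", "B", 2, 20)]
    tree = TreeNode(children=[leaf("a.1"), leaf("b.1"),
                              TreeNode(label="c.1", length=0.4)])
    recs.append(make_record("c", "D", 3, 5))
    groups = infer_groups(tree, recs)
    assert len(groups) == 3


def test_null_complement_leaf_becomes_excluded_singleton():
    recs = [make_record("u"), make_record("a", "A", 1, 1),
            make_record("b", "B", 1, 2)]
    tree = TreeNode(children=[leaf("u.1"), leaf("a.1"), leaf("b.1")])
    groups = infer_groups(tree, recs)
    unplaced = [g for g in groups if g.complement is None]
    assert len(unplaced) == 1 and unplaced[0].members[0].gene_id == "u"


def test_partition_property_every_copy_in_exactly_one_group():
    recs = [
        make_record("xA", "A", 4, 100), make_record("xB", "B", 4, 110),
        make_record("xD", "D", 4, 120), make_record("yA", "A", 4, 500),
        make_record("yD", "D", 4, 510),
    ]
    tree = TreeNode(children=[
        node(node(leaf("xA.1"), leaf("xB.1")), leaf("xD.1")),
        node(leaf("yA.1"), leaf("yD.1")),
        leaf_extra := TreeNode(label="zB.1", length=0.3),
    ])
    recs.append(make_record("zB", "B", 4, 900))
    groups = infer_groups(tree, recs)
    members = [m.record_id for g in groups for m in g.members]
    assert sorted(members) == sorted(r.record_id for r in recs)


def test_table1_type_counts_and_percentages(table1_groups):
    stats = type_groups(table1_groups)
    assert stats.type_copy_counts == {
        "A:B:D": 225, "A:B": 2, "A:D": 24, "B:D": 14, "A": 10, "B": 4, "D": 15,
    }
    assert stats.type_gene_counts == {
        "A:B:D": 75, "A:B": 1, "A:D": 12, "B:D": 7, "A": 10, "B": 4, "D": 15,
    }
    assert stats.total_copies == 294
    assert stats.total_genes == 124
    assert stats.type_gene_pct["A:B:D"] == 60.48
    assert stats.type_gene_pct["A:B"] == 0.81  # the lost-D share


def test_subgenome_copy_counts_from_type_configuration(table1_groups):
    stats = summary_stats(table1_groups)
    # A = 75+1+12+10, B = 75+1+7+4, D = 75+12+7+15
    assert stats.subgenome_copy_counts == {"A": 98, "B": 87, "D": 109}
    assert stats.subgenome_copy_pct == {"A": 33.33, "B": 29.59, "D": 37.07}


def test_empty_catalog_stats_are_all_zero():
    stats = summary_stats([])
    assert stats.total_copies == 0 and stats.total_genes == 0
    assert all(v == 0 for v in stats.type_copy_counts.values())


def test_fold_ratios_against_rice_and_maize():
    assert fold_ratio(294, 103) == 2.85
    assert fold_ratio(294, 119) == 2.47


def test_percentage_rounding_is_half_up():
    assert round_pct(75, 124) == 60.48
    assert round_pct(1, 124) == 0.81
    assert round_pct(109, 294) == 37.07
    assert round_pct(5, 1000) == 0.5
    assert round_pct(1, 0) == 0.0


def _named(groups, prefix="W"):
    return {g.base_name: g for g in assign_names(groups, prefix=prefix)}


def test_single_triad_names_all_subgenomes():
    g = infer_groups(
        TreeNode(children=[leaf("xA.1"), leaf("xB.1"), leaf("xD.1")]),
        [make_record("xA", "A", 1, 100), make_record("xB", "B", 1, 90),
         make_record("xD", "D", 1, 120)],
    )
    (group,) = assign_names(g, prefix="W")
    assert group.base_name == "W1"
    assert sorted(group.member_names.values()) == ["W1-A", "W1-B", "W1-D"]


def test_serials_follow_reference_subgenome_start_order():
    g1 = [make_record("aA", "A", 1, 500)]
    g2 = [make_record("bA", "A", 1, 100)]
    from familymap.homeolog import HomeologGroup

    groups = [
        HomeologGroup(g1, 1, "A"),
        HomeologGroup(g2, 1, "A"),
    ]
    named = assign_names(groups, prefix="W")
    assert [g.members[0].gene_id for g in named] == ["bA", "aA"]
    assert [g.serial for g in named] == [1, 2]


def test_complements_are_numbered_in_order():
    from familymap.homeolog import HomeologGroup

    groups = [
        HomeologGroup([make_record("c3", "A", 3, 10)], 3, "A"),
        HomeologGroup([make_record("c2x", "A", 2, 99)], 2, "A"),
        HomeologGroup([make_record("c2y", "B", 2, 1)], 2, "B"),
    ]
    named = assign_names(groups, prefix="W")
    serial = {g.members[0].gene_id: g.serial for g in named}
    assert serial["c3"] > max(serial["c2x"], serial["c2y"])


def test_naming_is_stable_under_input_permutation():
    def build():
        return [
            make_record("xA", "A", 2, 300), make_record("xB", "B", 2, 310),
            make_record("yA", "A", 2, 100), make_record("zD", "D", 1, 50),
        ]

    from familymap.homeolog import HomeologGroup

    def groups_from(recs):
        return [
            HomeologGroup([recs[0], recs[1]], 2, "A:B"),
            HomeologGroup([recs[2]], 2, "A"),
            HomeologGroup([recs[3]], 1, "D"),
        ]

    a = assign_names(groups_from(build()), prefix="W")
    b = assign_names(list(reversed(groups_from(build()))), prefix="W")
    names_a = sorted(n for g in a for n in g.member_names.values())
    names_b = sorted(n for g in b for n in g.member_names.values())
    assert names_a == names_b
    serial_a = {g.members[0].gene_id: g.serial for g in a}
    serial_b = {g.members[0].gene_id: g.serial for g in b}
    assert serial_a == serial_b
    # serials are a bijection onto 1..G
    assert sorted(serial_a.values()) == [1, 2, 3]


def test_unplaced_groups_are_numbered_last():
    from familymap.homeolog import HomeologGroup

    groups = [
        HomeologGroup([make_record("u")], None, "?"),
        HomeologGroup([make_record("a", "A", 7, 5)], 7, "A"),
    ]
    named = assign_names(groups, prefix="W")
    assert named[-1].complement is None and named[-1].serial == 2


def test_duplicate_subgenome_in_group_is_invariant_violation():
    from familymap.homeolog import HomeologGroup

    with pytest.raises(HomeologError, match="duplicate subgenome"):
        HomeologGroup(
            [make_record("a1", "A", 1, 1), make_record("a2", "A", 1, 2)],
            1, "A",
        )
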