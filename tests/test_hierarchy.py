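"""Tree construction, policies, invariants and JSON round trips."""

import json

import pytest

from functree import (HierarchyError, MembershipTables, SchemaError,
                      build_tree, dumps_tree, load_tree, loads_tree,
                      serialize_tree)
from functree.hierarchy import (UNDEFINED_CATEGORY_ID, UNDEFINED_PATHWAY_ID,
                                parse_pair_table, parse_skeleton_table)
from functree.synth import standard_config, make_membership


def test_smallest_mixed_case_placement(tiny_tree):
    """P under its process/category, M under P, K1 under M, K2 direct under
    P, K3 hidden under the Undefined category."""
    t = tiny_tree
    assert t.layer_of("P") == "pathway"
    p_pid = next(iter(t.by_function["P"]))
    children = {t.nodes[c].function_id: t.nodes[c].layer
                for c in t.nodes[p_pid].children}
    assert children == {"M": "module", "K2": "ko"}
    m_pid = next(iter(t.by_function["M"]))
    assert [t.nodes[c].function_id for c in t.nodes[m_pid].children] == ["K1"]
    k3_pid = next(iter(t.by_function["K3"]))
    assert t.nodes[k3_pid].hidden
    assert "K3" in t.function_ko_set(UNDEFINED_CATEGORY_ID)
    assert t.ko_universe == frozenset({"K1", "K2", "K3"})


def test_straddling_module_subset_vs_overlap(straddle_tables):
    subset = build_tree(straddle_tables, attach_policy="subset")
    # under subset, M is contained by neither pathway: it goes hidden and the
    # KOs reappear directly under their own pathways
    (m_pid,) = subset.by_function["M"]
    assert subset.nodes[m_pid].hidden
    assert UNDEFINED_PATHWAY_ID in m_pid
    for ko, p in (("K1", "P1"), ("K2", "P2")):
        p_pid = next(iter(subset.by_function[p]))
        assert ko in {subset.nodes[c].function_id
                      for c in subset.nodes[p_pid].children}

    overlap = build_tree(straddle_tables, attach_policy="overlap")
    placements = overlap.by_function["M"]
    assert len(placements) == 2
    assert {overlap.nodes[p].function_id for p in placements} == {"M"}
    parents = {p.rsplit("/", 1)[0].rsplit("/", 1)[-1] for p in placements}
    assert parents == {"P1", "P2"}


def test_duplicate_membership_rows_are_idempotent(tiny_tables):
    # frozenset-valued tables cannot hold duplicates; re-parsing duplicated
    # pair rows yields the identical tables, hence the identical tree
    text = "K1\tM\nK1\tM\n"
    assert parse_pair_table(text) == parse_pair_table("K1\tM\n")
    assert build_tree(tiny_tables) == build_tree(tiny_tables)


def test_empty_tables_rejected():
    with pytest.raises(HierarchyError, match="empty"):
        build_tree(MembershipTables({}, {}, {}, {}))


def test_self_referential_ids_rejected():
    tables = MembershipTables(
        ko_to_modules={"X": frozenset({"X"})},
        ko_to_pathways={"X": frozenset({"P"})},
        pathway_skeleton={"P": ("proc", "cat")},
        names={"X": "x", "P": "p"},
    )
    with pytest.raises(HierarchyError, match="X"):
        build_tree(tables)


def test_pathway_missing_from_skeleton_rejected():
    tables = MembershipTables(
        ko_to_modules={},
        ko_to_pathways={"K1": frozenset({"P9"})},
        pathway_skeleton={},
        names={"P9": "p"},
    )
    with pytest.raises(HierarchyError, match="P9"):
        build_tree(tables)


@pytest.mark.parametrize("seed", range(10))
def test_random_tables_satisfy_invariants(seed):
    """Layer order, leaf-KO union, hidden bookkeeping and zero KO loss on
    randomly generated membership tables."""
    cfg = standard_config(seed=seed, n_kos=60, n_pathways=6, n_modules=10,
                          unassigned_fraction=0.15)
    tables = make_membership(cfg)
    tree = build_tree(tables)
    tree.validate()  # layer order + leaf union + hidden flags + indices
    assert tree.ko_universe == tables.ko_universe()
    # unassigned KOs exactly fill the hidden subtree
    in_any = {k for k, v in tables.ko_to_modules.items() if v}
    in_any |= {k for k, v in tables.ko_to_pathways.items() if v}
    unassigned = tables.ko_universe() - in_any
    assert tree.function_ko_set(UNDEFINED_CATEGORY_ID) == unassigned


def test_build_is_deterministic_including_child_order():
    cfg = standard_config(seed=3, n_kos=80, n_pathways=6, n_modules=12)
    t1 = build_tree(make_membership(cfg))
    t2 = build_tree(make_membership(cfg))
    assert t1 == t2
    for pid, node in t1.nodes.items():
        kids = [t1.nodes[c].function_id for c in node.children]
        assert kids == sorted(kids)


def test_serialize_load_round_trip(tiny_tree):
    assert loads_tree(dumps_tree(tiny_tree)) == tiny_tree


def test_serialize_round_trip_random_trees():
    for seed in range(5):
        cfg = standard_config(seed=seed, n_kos=50, n_pathways=5, n_modules=8)
        tree = build_tree(make_membership(cfg))
        assert load_tree(json.loads(dumps_tree(tree))) == tree


def test_multi_placement_function_appears_once_per_placement(straddle_tables):
    tree = build_tree(straddle_tables, attach_policy="overlap")
    doc = json.dumps(serialize_tree(tree))
    assert doc.count('"id": "M"') == 2


def test_load_rejects_ko_under_category():
    doc = {"schema_version": 1, "root": {
        "id": "root", "name": "root", "layer": "root", "hidden": False,
        "children": [{
            "id": "cat", "name": "cat", "layer": "biological_category",
            "hidden": False,
            "children": [{"id": "K1", "name": "K1", "layer": "ko",
                          "hidden": False, "children": []}],
        }]}}
    with pytest.raises(SchemaError, match=r"children\[0\]"):
        load_tree(doc)


def test_load_rejects_missing_key_with_path():
    doc = {"schema_version": 1, "root": {
        "id": "root", "name": "root", "layer": "root", "hidden": False,
        "children": [{"id": "c", "layer": "biological_category",
                      "hidden": False, "children": []}]}}
    with pytest.raises(SchemaError, match=r"\$\.root\.children\[0\]\.name"):
        load_tree(doc)


def test_load_rejects_wrong_schema_version(tiny_tree):
    doc = serialize_tree(tiny_tree)
    doc["schema_version"] = 99
    with pytest.raises(SchemaError, match="schema_version"):
        load_tree(doc)


def test_load_accepts_empty_children_on_leaves(tiny_tree):
    doc = serialize_tree(tiny_tree)
    # every KO leaf serializes with an empty children array
    assert '"children": []' in json.dumps(doc, indent=1)
    load_tree(doc)


def test_skeleton_parser_rejects_reassignment():
    with pytest.raises(HierarchyError, match="re-assigned"):
        parse_skeleton_table("P1\ta\tb\nP1\tc\td\n")
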