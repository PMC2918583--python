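"""Reaction localization and relationship-type classification."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from compartnet.model import Network, Protein, Reaction
from compartnet.reaction_location import (
    assign_locations,
    classify,
    find_complementary_groups,
    localize_reactions,
    resolve_type_c,
)


def network_with(protein_locs: dict[str, set[str]], n_reactions: int = 1) -> Network:
    net = Network()
    for i in range(n_reactions):
        net.add_reaction(
            Reaction(f"R{i}", [(f"A{i}", 1.0)], [(f"B{i}", 1.0)], False, {"pw"})
        )
    for pid, locs in protein_locs.items():
        p = net.add_protein(Protein(pid))
        for code in locs:
            p.add_location(code, "GO")
        for i in range(n_reactions):
            net.add_link(pid, f"R{i}")
    return net


@pytest.mark.parametrize(
    "locs,expected",
    [
        ({"P1": {"C"}, "P2": {"M"}}, {"C", "M"}),     # union across enzymes
        ({"P1": {"X", "ER"}}, {"X", "ER"}),           # single enzyme, two sites
        ({"P1": {"U"}, "P2": {"M"}}, {"M"}),          # U dropped when real known
    ],
)
def test_assign_locations_union(locs, expected):
    net = network_with(locs)
    rxn = net.reactions["R0"]
    assign_locations(net, rxn)
    assert set(rxn.locations) == expected
    assert all(p == "protein" for p in rxn.locations.values())


def test_non_enzymatic_reaction_defaults_to_uncertain():
    net = network_with({})
    rxn = net.reactions["R0"]
    assign_locations(net, rxn)
    assert rxn.locations == {"U": "default-uncertain"}


def test_all_uncertain_enzymes_default_to_uncertain():
    net = network_with({"P1": {"U"}})
    rxn = net.reactions["R0"]
    assign_locations(net, rxn)
    assert rxn.locations == {"U": "default-uncertain"}


@pytest.mark.parametrize(
    "locs,expected",
    [
        ({"P1": {"L"}}, "a"),                                  # one protein
        ({"P1": {"M"}, "P2": {"M"}}, "b"),                     # identical sets
        ({"P1": {"C"}, "P2": {"M"}}, "c"),                     # disjoint sets
        ({"P1": {"GA", "E"}, "P2": {"GA"}, "P3": {"GA"}}, "d"),  # common + unique
        ({"P1": {"C", "M"}, "P2": {"M", "X"}, "P3": {"E"}}, "d"),  # mixed residual
        ({"P1": {"U"}, "P2": {"U"}}, "unknown"),               # no information
        ({"P1": {"U"}, "P2": {"M"}}, "a"),                     # U-protein excluded
    ],
)
def test_classify_types(locs, expected):
    net = network_with(locs)
    assert classify(net, "R0") == expected


def test_unlinked_reaction_is_unclassified():
    net = network_with({})
    assert classify(net, "R0") is None


def test_classify_invariant_under_protein_order():
    locs = {"P1": {"C"}, "P2": {"M"}, "P3": {"GA", "E"}}
    results = set()
    for order in itertools.permutations(locs):
        net = network_with({pid: locs[pid] for pid in order})
        results.add(classify(net, "R0"))
    assert len(results) == 1


@settings(max_examples=60, derandomize=True)
@given(
    st.lists(
        st.sets(st.sampled_from(["C", "M", "X", "ER", "U"]), min_size=1, max_size=3),
        min_size=1,
        max_size=4,
    )
)
def test_classify_matches_literal_definition(loc_sets):
    """Cross-check against a direct restatement of the type definitions."""
    locs = {f"P{i}": s for i, s in enumerate(loc_sets)}
    net = network_with(locs)
    got = classify(net, "R0")

    informative = [frozenset(s - {"U"}) for s in loc_sets if s - {"U"}]
    if not informative:
        expected = "unknown"
    elif len(informative) == 1:
        expected = "a"
    elif len(set(informative)) == 1:
        expected = "b"
    elif all(
        a.isdisjoint(b) for a, b in itertools.combinations(set(informative), 2)
    ):
        expected = "c"
    else:
        expected = "d"
    assert got == expected


def test_complementary_groups_aggregate_by_partition():
    net = network_with({"P1": {"C"}, "P2": {"M"}}, n_reactions=2)
    groups = find_complementary_groups(net)
    assert len(groups) == 1
    assert groups[0].reaction_ids == {"R0", "R1"}
    parts = {(tuple(sorted(p)), tuple(sorted(l))) for p, l in groups[0].parts}
    assert parts == {(("P1",), ("C",)), (("P2",), ("M",))}


def test_no_type_c_reactions_yields_no_groups():
    net = network_with({"P1": {"M"}, "P2": {"M"}})
    assert find_complementary_groups(net) == []


def test_resolve_type_c_deactivates_wrong_part(worked):
    groups = find_complementary_groups(worked)
    group = next(g for g in groups if "RE3139" in g.reaction_ids)
    deletions = resolve_type_c(worked, group, "X")
    assert len(deletions) == 3
    assert {d.protein_id for d in deletions} == {"ACAA2", "HADHA", "HADHB"}
    rxn = worked.reactions["RE3139"]
    assert rxn.locations == {"X": "curated"}
    assert classify(worked, "RE3139") in ("a", "b")
    # links are soft-deleted, not removed
    assert len(worked.links_for_reaction("RE3139", active_only=False)) == 4
    assert len(worked.links_for_reaction("RE3139")) == 1


def test_resolve_type_c_rejects_foreign_verdict():
    net = network_with({"P1": {"C"}, "P2": {"M"}})
    group = find_complementary_groups(net)[0]
    with pytest.raises(ValueError, match="verdict"):
        resolve_type_c(net, group, "GA")


def test_resolve_type_c_scales_with_group_size():
    """A two-reaction group with a k-protein wrong part yields 2*k deletions."""
    net = network_with({"P1": {"M"}, "P2": {"X"}, "P3": {"X"}}, n_reactions=2)
    group = find_complementary_groups(net)[0]
    deletions = resolve_type_c(net, group, "M")
    assert len(deletions) == 4


def test_localize_reactions_marks_network(single_gap):
    assert single_gap.localized
    assert set(single_gap.reactions["R1"].locations) == {"M"}
    assert set(single_gap.reactions["R6"].locations) == {"U"}
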