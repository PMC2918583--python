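"""Pathway-location graphs, components and cross-compartment path search."""

import random

import networkx as nx
import numpy as np
import pytest

from compartnet.model import Network, Reaction, TransportReaction
from compartnet.pathway_graph import (
    PathwayLocationGraph,
    build_graph,
    component_metabolites,
    components,
    find_path,
    to_dot,
    to_edge_list,
)


def chain_network(located: str = "M") -> Network:
    """A -> B -> C -> D as three irreversible reactions in one compartment."""
    net = Network()
    for i, (s, p) in enumerate([("A", "B"), ("B", "C"), ("C", "D")], 1):
        rxn = Reaction(f"R{i}", [(s, 1.0)], [(p, 1.0)], False, {"pw"})
        rxn.set_location(located, "protein")
        net.add_reaction(rxn)
    net.localized = True
    return net


def test_linear_chain_is_one_component():
    net = chain_network()
    g = build_graph(net, "pw", "M", currency=frozenset())
    assert g.graph.number_of_edges() == 2
    assert components(g) == [["R1", "R2", "R3"]]


def test_currency_metabolite_breaks_linking():
    net = chain_network()
    g = build_graph(net, "pw", "M", currency=frozenset({"B"}))
    assert g.graph.number_of_edges() == 1
    assert components(g) == [["R1"], ["R2", "R3"]]


def test_flow_rule_does_not_join_parallel_consumers():
    """Two reactions consuming the same substrate never flow into each
    other; the co-occurrence variant links them."""
    net = Network()
    for rid, prod in (("R1", "B"), ("R2", "C")):
        rxn = Reaction(rid, [("A", 1.0)], [(prod, 1.0)], False, {"pw"})
        rxn.set_location("M", "protein")
        net.add_reaction(rxn)
    net.localized = True
    flow = build_graph(net, "pw", "M", currency=frozenset())
    assert flow.graph.number_of_edges() == 0
    co = build_graph(net, "pw", "M", currency=frozenset(), edge_rule="cooccurrence")
    assert co.graph.number_of_edges() == 1


def test_reversible_reaction_permits_both_directions():
    net = chain_network()
    # reverse R2's roles (consume C, produce B): with no direction freedom
    # nothing flows, reversibility restores both links
    net.reactions["R2"].substrates = [("C", 1.0)]
    net.reactions["R2"].products = [("B", 1.0)]
    g = build_graph(net, "pw", "M", currency=frozenset())
    assert [len(c) for c in components(g)] == [1, 1, 1]
    net.reactions["R2"].reversible = True
    g2 = build_graph(net, "pw", "M", currency=frozenset())
    assert components(g2) == [["R1", "R2", "R3"]]


def test_build_graph_errors():
    net = chain_network()
    with pytest.raises(KeyError):
        build_graph(net, "nope", "M")
    with pytest.raises(ValueError):
        build_graph(net, "pw", "U")


def test_single_gap_topology_two_components(single_gap):
    g = build_graph(single_gap, "example-pathway", "M")
    assert [len(c) for c in components(g)] == [5, 1]


def test_component_metabolites_union():
    net = chain_network()
    g = build_graph(net, "pw", "M", currency=frozenset({"X"}))
    comp = components(g)[0]
    assert component_metabolites(g, comp) == {"A", "B", "C", "D"}
    with pytest.raises(KeyError):
        component_metabolites(g, ["R99"])


def test_edgeless_graph_has_singleton_components():
    plg = PathwayLocationGraph("pw", "M")
    for n in "abcd":
        plg.graph.add_node(n, mets=set())
    assert components(plg) == [["a"], ["b"], ["c"], ["d"]]


def closure_components(n: int, edges: list[tuple[int, int]]) -> list[set[int]]:
    """Reachability by boolean matrix squaring (independent oracle)."""
    reach = np.eye(n, dtype=bool)
    for u, v in edges:
        reach[u, v] = reach[v, u] = True
    for _ in range(int(np.ceil(np.log2(max(n, 2)))) + 1):
        reach = reach @ reach
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if reach[i, j]}
        seen |= comp
        comps.append(comp)
    return comps


def test_components_match_transitive_closure_on_random_graphs():
    rng = random.Random(1234)
    for _ in range(500):
        n = rng.randint(1, 50)
        p = rng.random() * 0.15
        edges = [
            (u, v) for u in range(n) for v in range(u + 1, n) if rng.random() < p
        ]
        plg = PathwayLocationGraph("pw", "M")
        for i in range(n):
            plg.graph.add_node(f"n{i:02d}", mets=set())
        for u, v in edges:
            plg.graph.add_edge(f"n{u:02d}", f"n{v:02d}", metabolites=set())
        got = [set(c) for c in components(plg)]
        expected = [
            {f"n{i:02d}" for i in comp} for comp in closure_components(n, edges)
        ]
        assert sorted(map(sorted, got)) == sorted(map(sorted, expected))
        assert sum(len(c) for c in got) == n


def test_adding_edges_never_increases_component_count():
    rng = random.Random(99)
    plg = PathwayLocationGraph("pw", "M")
    for i in range(30):
        plg.graph.add_node(i, mets=set())
    previous = len(components(plg))
    for _ in range(60):
        u, v = rng.sample(range(30), 2)
        plg.graph.add_edge(u, v, metabolites=set())
        now = len(components(plg))
        assert now <= previous
        previous = now


def test_build_graph_invariant_to_reaction_order():
    net1 = chain_network()
    net2 = Network()
    for rid in ("R3", "R1", "R2"):
        src = net1.reactions[rid]
        rxn = Reaction(rid, list(src.substrates), list(src.products), False, {"pw"})
        rxn.set_location("M", "protein")
        net2.add_reaction(rxn)
    net2.localized = True
    g1 = build_graph(net1, "pw", "M", currency=frozenset())
    g2 = build_graph(net2, "pw", "M", currency=frozenset())
    assert components(g1) == components(g2)
    assert to_edge_list(g1) == to_edge_list(g2)


# ---------------------------------------------------------------------------
# Path search


def transported_network() -> Network:
    """A@C --transport--> A@M --reaction--> B@M."""
    net = Network()
    r = Reaction("RB", [("A", 1.0)], [("B", 1.0)], False, {"pw"})
    r.set_location("M", "protein")
    net.add_reaction(r)
    r2 = Reaction("RC", [("Z", 1.0)], [("A", 1.0)], False, {"pw"})
    r2.set_location("C", "protein")
    net.add_reaction(r2)
    net.localized = True
    net.transports.append(TransportReaction("T_A_C_M", "A", "C", "M"))
    return net


def test_forced_two_step_route():
    net = transported_network()
    steps = find_path(net, ("A", "C"), ("B", "M"), currency=frozenset())
    assert [s.reaction_id for s in steps] == ["T_A_C_M", "RB"]
    assert [s.compartment for s in steps] == ["M", "M"]


def test_unreachable_returns_none():
    net = transported_network()
    net.transports.clear()
    net.reactions["RB"].set_location("C", "protein")  # make B exist somewhere
    assert find_path(net, ("A", "M"), ("Z", "C"), currency=frozenset()) is None


def test_absent_endpoint_rejected():
    net = transported_network()
    with pytest.raises(ValueError, match="absent"):
        find_path(net, ("A", "GA"), ("B", "M"), currency=frozenset())


def test_alternating_compartment_synthesis_route():
    """Biosynthesis shapes that shuttle an intermediate back and forth
    (cytosol -> mitochondrion -> cytosol -> mitochondrion) are traversed in
    compartment order."""
    net = Network()
    spec = [
        ("R1", "ser", "ala5", "M"),
        ("R2", "ala5", "copro", "C"),
        ("R3", "copro", "heme", "M"),
    ]
    for rid, s, p, comp in spec:
        r = Reaction(rid, [(s, 1.0)], [(p, 1.0)], False, {"heme"})
        r.set_location(comp, "protein")
        net.add_reaction(r)
    rs = Reaction("R0", [("glc", 1.0)], [("ser", 1.0)], False, {"heme"})
    rs.set_location("C", "protein")
    net.add_reaction(rs)
    net.localized = True
    for met in ("ser", "ala5", "copro"):
        net.transports.append(TransportReaction(f"T_{met}", met, "C", "M"))
    steps = find_path(net, ("glc", "C"), ("heme", "M"), currency=frozenset())
    comps = [s.compartment for s in steps]
    assert comps == ["C", "M", "M", "C", "C", "M", "M"]
    assert steps[-1].metabolite_id == "heme"


def test_dot_export_is_deterministic():
    net = chain_network()
    g = build_graph(net, "pw", "M", currency=frozenset())
    assert to_dot(g) == to_dot(g)
    assert '"R1" -- "R2" [label="B"];' in to_dot(g)
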