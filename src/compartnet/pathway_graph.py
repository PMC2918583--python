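"""Per-pathway, per-compartment reaction graphs and path search.

For one pathway and one compartment, the reactions of the pathway located
in that compartment become nodes of an undirected graph; two reactions are
linked when a shared *main* (non-currency) metabolite can flow from one to
the other — produced by one and consumed by the other under at least one
permitted direction (reversible reactions permit both). Connected
components of these graphs are the unit of the gap and isolated-reaction
analyses.

Currency metabolites (ATP, NADH, water, ...) are excluded from linking:
they appear in so many reactions that keeping them would weld almost any
two reactions together and hide the real pathway structure.

A simpler co-occurrence edge rule (shared main metabolite regardless of
role) is available for sensitivity analysis via ``edge_rule``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .model import ISOLATED_PATHWAY, Network, check_compartment

EDGE_RULE_FLOW = "flow"
EDGE_RULE_COOCCURRENCE = "cooccurrence"

#: Default currency metabolites: ubiquitous cofactors and small carriers.
DEFAULT_CURRENCY: frozenset[str] = frozenset(
    {
        "ATP",
        "ADP",
        "AMP",
        "NAD+",
        "NADH",
        "NADP+",
        "NADPH",
        "FAD",
        "FADH2",
        "CoA",
        "H2O",
        "CO2",
        "O2",
        "NH3",
        "Orthophosphate",
        "Pyrophosphate",
        "H+",
    }
)


@dataclass
class PathwayLocationGraph:
    """Reactions of one pathway restricted to one compartment."""

    pathway: str
    compartment: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def components(self) -> list[list[str]]:
        return components(self)

    def node_metabolites(self, reaction_id: str) -> set[str]:
        return self.graph.nodes[reaction_id]["mets"]


def build_graph(
    network: Network,
    pathway: str,
    compartment: str,
    currency: Iterable[str] = DEFAULT_CURRENCY,
    edge_rule: str = EDGE_RULE_FLOW,
) -> PathwayLocationGraph:
    """Build the reaction graph of one (pathway, compartment) pair.

    Node attribute ``mets`` stores each reaction's main metabolites; edge
    attribute ``metabolites`` stores the shared main metabolites that carry
    the link.
    """
    check_compartment(compartment)
    if compartment == "U":
        raise ValueError("the uncertain placeholder has no pathway graph")
    if pathway not in network.pathway_index:
        raise KeyError(f"unknown pathway: {pathway!r}")
    if edge_rule not in (EDGE_RULE_FLOW, EDGE_RULE_COOCCURRENCE):
        raise ValueError(f"unknown edge rule: {edge_rule!r}")

    currency = frozenset(currency)
    plg = PathwayLocationGraph(pathway=pathway, compartment=compartment)
    members = [
        r for r in network.pathway_reactions(pathway) if compartment in r.locations
    ]
    for r in members:
        plg.graph.add_node(r.id, mets=r.main_metabolites(currency))
    for r1, r2 in combinations(members, 2):
        if edge_rule == EDGE_RULE_FLOW:
            shared = (r1.producible() & r2.consumable()) | (
                r2.producible() & r1.consumable()
            )
        else:
            shared = r1.metabolite_ids & r2.metabolite_ids
        shared -= currency
        if shared:
            plg.graph.add_edge(r1.id, r2.id, metabolites=shared)
    return plg


def components(graph: PathwayLocationGraph) -> list[list[str]]:
    """Connected components in canonical order.

    Each component is a sorted list of reaction ids; components are ordered
    by their smallest member id, so repeated runs agree byte for byte.
    """
    comps = [sorted(c) for c in nx.connected_components(graph.graph)]
    comps.sort(key=lambda c: c[0])
    return comps


def component_metabolites(
    graph: PathwayLocationGraph, component: Sequence[str]
) -> set[str]:
    """Union of main metabolites over one component's member reactions."""
    mets: set[str] = set()
    for rid in component:
        if rid not in graph.graph:
            raise KeyError(f"reaction {rid!r} not in graph {graph.pathway}/{graph.compartment}")
        mets |= graph.graph.nodes[rid]["mets"]
    return mets


# ---------------------------------------------------------------------------
# Cross-compartment path search


@dataclass
class PathStep:
    reaction_id: str
    compartment: str
    metabolite_id: str  # the metabolite carried into this step's output


def _state_graph(network: Network, currency: frozenset[str]) -> nx.DiGraph:
    """Directed graph over (metabolite, compartment) states.

    A metabolic reaction located in compartment K maps each main substrate
    state to each main product state within K (both directions when
    reversible); transport reactions map the moved metabolite between
    compartments. Currency metabolites are non-traversable carriers and
    never become states.
    """
    g = nx.DiGraph()

    def add_edge(u, v, rid):
        if g.has_edge(u, v):
            g.edges[u, v]["reactions"].add(rid)
        else:
            g.add_edge(u, v, reactions={rid})

    for rxn in network.reactions.values():
        subs = rxn.substrate_ids - currency
        prods = rxn.product_ids - currency
        for comp in rxn.locations:
            if comp == "U":
                continue
            for s in subs:
                for p in prods:
                    add_edge((s, comp), (p, comp), rxn.id)
                    if rxn.reversible:
                        add_edge((p, comp), (s, comp), rxn.id)
    for t in network.transports:
        u = (t.metabolite_id, t.comp_from)
        v = (t.metabolite_id, t.comp_to)
        add_edge(u, v, t.id)
        if t.reversible:
            add_edge(v, u, t.id)
    return g


def find_path(
    network: Network,
    source: tuple[str, str],
    target: tuple[str, str],
    currency: Iterable[str] = DEFAULT_CURRENCY,
) -> list[PathStep] | None:
    """Shortest directed route (by reaction count) between two
    metabolite@compartment endpoints, or ``None`` when unreachable.

    Transport reactions appear as steps that change compartment only. Meant
    to be run after transport addition; raises ``ValueError`` when an
    endpoint metabolite is absent from its stated compartment.
    """
    currency = frozenset(currency)
    for met, comp in (source, target):
        check_compartment(comp)
        if comp == "U":
            raise ValueError("path endpoints must be in a real compartment")
        if comp not in network.metabolite_compartments(met, include_transports=True):
            raise ValueError(f"metabolite {met!r} absent from compartment {comp}")

    g = _state_graph(network, currency)
    src = (source[0], source[1])
    dst = (target[0], target[1])
    if src not in g or dst not in g:
        return None
    try:
        states = nx.shortest_path(g, src, dst)
    except nx.NetworkXNoPath:
        return None
    steps: list[PathStep] = []
    for u, v in zip(states, states[1:]):
        rid = sorted(g.edges[u, v]["reactions"])[0]
        steps.append(PathStep(reaction_id=rid, compartment=v[1], metabolite_id=v[0]))
    return steps


# ---------------------------------------------------------------------------
# Exports


def to_edge_list(graph: PathwayLocationGraph) -> list[tuple[str, str, str]]:
    """Deterministic (u, v, shared-metabolites) rows for TSV export."""
    rows = []
    for u, v, data in graph.graph.edges(data=True):
        a, b = sorted((u, v))
        rows.append((a, b, ";".join(sorted(data["metabolites"]))))
    return sorted(rows)


def to_dot(graph: PathwayLocationGraph) -> str:
    """Graphviz DOT rendering of one pathway-location graph."""
    lines = [f'graph "{graph.pathway}__{graph.compartment}" {{']
    for node in sorted(graph.graph.nodes):
        lines.append(f'    "{node}";')
    for a, b, mets in to_edge_list(graph):
        lines.append(f'    "{a}" -- "{b}" [label="{mets}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
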