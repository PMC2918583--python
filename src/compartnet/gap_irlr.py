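"""Connectivity-based revision: gap filling and isolated reaction-location
relationships (IRLRs).

A *gap* is a missing reaction-location relationship, not a missing
reaction: a reaction of a pathway that is **not** assigned to a compartment
but whose main metabolites touch two distinct connected components of that
compartment's pathway graph would, if assigned there, join the components.
Gaps whose reaction is otherwise location-less (``{U}``) are filled
automatically; gaps whose reaction already has a real location are filled
only on explicit literature evidence.

An *IRLR* is a reaction forming a one-node component in a compartment's
pathway graph. By default a reaction must be isolated in **every** pathway
containing it (for that compartment) to be flagged — a reaction connected
in any pathway context is considered functional there. Flagged IRLRs are
kept on literature evidence, kept when a catalysing protein exists only in
that compartment and catalyses nothing else, attributed to a bad
protein-reaction link when evidence says so, and removed otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

from .model import (
    PROV_DEFAULT_UNCERTAIN,
    PROV_GAP_FILLED,
    REAL_COMPARTMENTS,
    Network,
)
from .pathway_graph import (
    DEFAULT_CURRENCY,
    EDGE_RULE_FLOW,
    build_graph,
    component_metabolites,
    components,
)
from .reaction_location import recompute_locations

logger = logging.getLogger(__name__)

ACTION_AUTO = "auto-filled"
ACTION_EVIDENCE = "evidence-filled"
ACTION_UNFILLED = "unfilled"

DECISION_KEEP_EVIDENCE = "keep-evidence"
DECISION_KEEP_UNIQUE = "keep-unique-protein"
DECISION_REMOVE = "remove"
DECISION_REMOVE_BAD_LINK = "remove-bad-link"


# ---------------------------------------------------------------------------
# Gaps


@dataclass
class GapRecord:
    """One (reaction, pathway, compartment, component-pair) finding."""

    reaction_id: str
    pathway: str
    compartment: str
    component_pair: tuple[str, str]  # smallest member id of each component
    locations_at_detection: frozenset[str]
    action: str = ""
    citation: str = ""

    @property
    def fill_key(self) -> tuple[str, str]:
        return (self.reaction_id, self.compartment)


@dataclass
class GapEvidence:
    """Literature support for filling one (reaction, compartment) gap;
    optionally names new catalysing proteins to link."""

    reaction_id: str
    compartment: str
    new_proteins: tuple[str, ...] = ()
    citation: str = ""


def identify_gaps(
    network: Network,
    currency: Iterable[str] = DEFAULT_CURRENCY,
    edge_rule: str = EDGE_RULE_FLOW,
) -> list[GapRecord]:
    """Scan every (pathway, compartment) graph for bridgeable gaps.

    For each pathway reaction *not* located in the compartment, one record
    is emitted per pair of distinct components whose main-metabolite lists
    both intersect the reaction's main metabolites. A reaction may be a gap
    in several compartments, and one fill may close several records.
    """
    currency = frozenset(currency)
    records: list[GapRecord] = []
    for pathway in network.analysis_pathways():
        members = network.pathway_reactions(pathway)
        for compartment in REAL_COMPARTMENTS:
            graph = build_graph(network, pathway, compartment, currency, edge_rule)
            comps = components(graph)
            if len(comps) < 2:
                continue
            comp_mets = [component_metabolites(graph, c) for c in comps]
            for reaction in members:
                if compartment in reaction.locations:
                    continue
                mains = reaction.main_metabolites(currency)
                touching = [i for i, mets in enumerate(comp_mets) if mets & mains]
                for i, j in combinations(touching, 2):
                    records.append(
                        GapRecord(
                            reaction_id=reaction.id,
                            pathway=pathway,
                            compartment=compartment,
                            component_pair=(comps[i][0], comps[j][0]),
                            locations_at_detection=frozenset(reaction.locations),
                        )
                    )
    records.sort(
        key=lambda r: (r.pathway, r.compartment, r.reaction_id, r.component_pair)
    )
    return records


def fill_gaps(
    network: Network,
    gaps: list[GapRecord],
    evidence: Mapping[tuple[str, str], GapEvidence] | None = None,
) -> dict[str, int]:
    """Apply the fill rules, mutating the network and annotating records.

    A gap whose reaction was location-less (``{U}``) at detection time is
    filled directly (``auto-filled``); a gap on a reaction with real
    locations is filled only when an evidence row exists
    (``evidence-filled``, optionally adding the row's new protein links);
    everything else stays ``unfilled``. Fills of one reaction into one
    compartment are deduplicated across records.

    Returns per-action record counts plus ``fills`` (distinct
    reaction-compartment pairs added).
    """
    evidence = dict(evidence or {})
    for (rid, comp), ev in evidence.items():
        if rid not in network.reactions:
            raise KeyError(f"gap evidence references unknown reaction {rid!r}")
        for pid in ev.new_proteins:
            if pid not in network.proteins:
                raise KeyError(f"gap evidence references unknown protein {pid!r}")

    counts = {ACTION_AUTO: 0, ACTION_EVIDENCE: 0, ACTION_UNFILLED: 0, "fills": 0}
    filled: set[tuple[str, str]] = set()
    for record in gaps:
        reaction = network.reactions[record.reaction_id]
        key = record.fill_key
        if record.locations_at_detection == frozenset({"U"}):
            record.action = ACTION_AUTO
            counts[ACTION_AUTO] += 1
            if key not in filled:
                reaction.drop_location("U")
                reaction.set_location(record.compartment, PROV_GAP_FILLED)
                filled.add(key)
                counts["fills"] += 1
        elif key in evidence:
            ev = evidence[key]
            record.action = ACTION_EVIDENCE
            record.citation = ev.citation
            counts[ACTION_EVIDENCE] += 1
            if key not in filled:
                reaction.set_location(record.compartment, PROV_GAP_FILLED)
                for pid in ev.new_proteins:
                    if network.get_link(pid, record.reaction_id) is None:
                        network.add_link(pid, record.reaction_id)
                filled.add(key)
                counts["fills"] += 1
        else:
            record.action = ACTION_UNFILLED
            counts[ACTION_UNFILLED] += 1
    return counts


# ---------------------------------------------------------------------------
# IRLRs


@dataclass
class IRLRRecord:
    """A reaction isolated in one compartment, with its protein context."""

    reaction_id: str
    compartment: str
    pathways: tuple[str, ...]
    proteins: tuple[str, ...] = ()  # active proteins located in compartment
    protein_other_locations: dict[str, tuple[str, ...]] = field(default_factory=dict)
    protein_other_reactions: dict[str, tuple[str, ...]] = field(default_factory=dict)
    decision: str = ""
    citation: str = ""


@dataclass
class IRLREvidence:
    reaction_id: str
    compartment: str
    verdict: str  # "keep" | "bad-link"
    protein_id: str = ""  # required for bad-link
    citation: str = ""


SCOPE_ALL_PATHWAYS = "all-pathways"
SCOPE_PER_PATHWAY = "per-pathway"


def identify_irlrs(
    network: Network,
    currency: Iterable[str] = DEFAULT_CURRENCY,
    edge_rule: str = EDGE_RULE_FLOW,
    scope: str = SCOPE_ALL_PATHWAYS,
) -> list[IRLRRecord]:
    """Find one-node components in the location-specific pathway graphs.

    With the default ``all-pathways`` scope a (reaction, compartment) pair
    is flagged only when the reaction is a singleton in *every* analysed
    pathway containing it; ``per-pathway`` flags each pathway context
    separately.
    """
    if scope not in (SCOPE_ALL_PATHWAYS, SCOPE_PER_PATHWAY):
        raise ValueError(f"unknown IRLR scope: {scope!r}")
    currency = frozenset(currency)

    # singleton status per (reaction, compartment, pathway)
    singleton: dict[tuple[str, str], dict[str, bool]] = {}
    for pathway in network.analysis_pathways():
        for compartment in REAL_COMPARTMENTS:
            graph = build_graph(network, pathway, compartment, currency, edge_rule)
            for comp in components(graph):
                for rid in comp:
                    singleton.setdefault((rid, compartment), {})[pathway] = (
                        len(comp) == 1
                    )

    records: list[IRLRRecord] = []
    for (rid, compartment), by_pathway in sorted(singleton.items()):
        if scope == SCOPE_ALL_PATHWAYS:
            if all(by_pathway.values()):
                records.append(
                    _irlr_record(network, rid, compartment, tuple(sorted(by_pathway)))
                )
        else:
            for pathway, is_single in sorted(by_pathway.items()):
                if is_single:
                    records.append(
                        _irlr_record(network, rid, compartment, (pathway,))
                    )
    records.sort(key=lambda r: (r.pathways, r.compartment, r.reaction_id))
    return records


def _irlr_record(
    network: Network, reaction_id: str, compartment: str, pathways: tuple[str, ...]
) -> IRLRRecord:
    proteins = []
    other_locs: dict[str, tuple[str, ...]] = {}
    other_rxns: dict[str, tuple[str, ...]] = {}
    for link in network.links_for_reaction(reaction_id):
        protein = network.proteins[link.protein_id]
        if compartment not in protein.locations:
            continue
        proteins.append(protein.id)
        other_locs[protein.id] = tuple(sorted(protein.location_codes - {compartment}))
        other_rxns[protein.id] = tuple(
            sorted(
                l.reaction_id
                for l in network.links_for_protein(protein.id)
                if l.reaction_id != reaction_id
            )
        )
    return IRLRRecord(
        reaction_id=reaction_id,
        compartment=compartment,
        pathways=pathways,
        proteins=tuple(sorted(proteins)),
        protein_other_locations=other_locs,
        protein_other_reactions=other_rxns,
    )


def decide_irlrs(
    network: Network,
    irlrs: list[IRLRRecord],
    evidence: Mapping[tuple[str, str], IRLREvidence] | None = None,
) -> dict[str, int]:
    """Apply the keep/remove decision rules to flagged IRLRs.

    Per record, the first matching rule wins: literature *keep* evidence;
    *bad-link* evidence (the named link is deactivated and the reaction
    re-localized); a catalysing protein unique to the compartment and to
    this reaction; otherwise the compartment is removed from the reaction.
    A removal that would empty the location set reverts the reaction to
    ``{U}``.
    """
    evidence = dict(evidence or {})
    counts = {
        DECISION_KEEP_EVIDENCE: 0,
        DECISION_KEEP_UNIQUE: 0,
        DECISION_REMOVE: 0,
        DECISION_REMOVE_BAD_LINK: 0,
    }
    for record in irlrs:
        reaction = network.reactions[record.reaction_id]
        ev = evidence.get((record.reaction_id, record.compartment))
        if ev is not None and ev.verdict not in ("keep", "bad-link"):
            raise ValueError(
                f"IRLR evidence verdict must be keep or bad-link, got {ev.verdict!r}"
            )
        if ev is not None and ev.verdict == "keep":
            record.decision = DECISION_KEEP_EVIDENCE
            record.citation = ev.citation
        elif ev is not None and ev.verdict == "bad-link":
            link = network.get_link(ev.protein_id, record.reaction_id)
            if link is None:
                raise KeyError(
                    f"bad-link evidence names unknown link "
                    f"({ev.protein_id}, {record.reaction_id})"
                )
            link.active = False
            link.note = "IRLR revision: incorrect protein-reaction relationship"
            recompute_locations(network, reaction)
            record.decision = DECISION_REMOVE_BAD_LINK
            record.citation = ev.citation
        elif _has_unique_protein(network, record):
            record.decision = DECISION_KEEP_UNIQUE
        else:
            reaction.drop_location(record.compartment)
            if not reaction.locations:
                reaction.locations = {"U": PROV_DEFAULT_UNCERTAIN}
                logger.info(
                    "reaction %s reverted to uncertain after IRLR removal of %s",
                    record.reaction_id,
                    record.compartment,
                )
            record.decision = DECISION_REMOVE
        counts[record.decision] += 1
    return counts


def _has_unique_protein(network: Network, record: IRLRRecord) -> bool:
    """True if some catalysing protein exists only in the flagged
    compartment and catalyses no other reaction (active links,
    network-wide)."""
    for pid in record.proteins:
        protein = network.proteins[pid]
        if protein.location_codes == {record.compartment} and not record.protein_other_reactions.get(pid):
            return True
    return False
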