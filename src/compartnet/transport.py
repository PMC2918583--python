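"""Transport reactions: reference import, dead-end analysis, inference.

After the structural revisions, three steps connect the compartments:

1. every remaining ``{U}`` reaction is reassigned to the cytosol (the
   uncertain placeholder cannot participate in transport);
2. a scored reference list of transport reactions is imported — direct
   experimental evidence (score 3, and curated transporter annotations) is
   accepted whenever the metabolite is known to the network, physiological
   evidence (score 2) only when the metabolite already occurs in both
   compartments, and weaker scores are ignored;
3. *dead ends* — metabolites only produced, only consumed, or confined to a
   single reaction within a compartment — are detected, and for each
   dead-end metabolite present in several compartments reversible
   transports are added with the cytosol as bridging hub.

Inferred transports are reversible: dead-end analysis carries no
directional evidence and reversibility guarantees the connectivity goal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .model import (
    PROV_CYTOSOL_DEFAULT,
    REAL_COMPARTMENTS,
    Network,
    TransportReaction,
    TRANSPORT_SOURCES,
    check_compartment,
)
from .pathway_graph import DEFAULT_CURRENCY

logger = logging.getLogger(__name__)

MODE_ONLY_PRODUCED = "only-produced"
MODE_ONLY_CONSUMED = "only-consumed"
MODE_SOLE_PARTICIPANT = "sole-participant"


# ---------------------------------------------------------------------------
# Uncertain -> cytosol


def reassign_uncertain(network: Network) -> int:
    """Move every purely-uncertain reaction to the cytosol.

    Reactions located exactly ``{U}`` become ``{C}`` (provenance
    ``cytosol-default``); a redundant ``U`` alongside real compartments is
    simply dropped. Returns the number of reactions reassigned.
    """
    moved = 0
    for reaction in network.reactions.values():
        if set(reaction.locations) == {"U"}:
            reaction.locations = {"C": PROV_CYTOSOL_DEFAULT}
            moved += 1
        elif "U" in reaction.locations:
            reaction.drop_location("U")
    return moved


# ---------------------------------------------------------------------------
# Reference import


@dataclass
class ReferenceTransport:
    """A candidate transport from an external reference with a 0-3
    confidence score; ``transporter_annotation`` marks rows derived from
    curated transporter databases (accepted like direct evidence)."""

    metabolite_id: str
    comp_from: str
    comp_to: str
    score: int
    protein_ids: tuple[str, ...] = ()
    reversible: bool = True
    transporter_annotation: bool = False


@dataclass
class RejectedTransport:
    candidate: ReferenceTransport
    reason: str


def transport_id(metabolite_id: str, comp_a: str, comp_b: str) -> str:
    """Deterministic transport-reaction identifier for one metabolite and
    one unordered compartment pair."""
    a, b = sorted((comp_a, comp_b))
    return f"T_{metabolite_id}_{a}_{b}"


def import_reference(
    network: Network, reference: Iterable[ReferenceTransport]
) -> tuple[list[TransportReaction], list[RejectedTransport]]:
    """Filter a scored reference list into accepted transport reactions.

    Score 3 (or transporter-annotation) rows are accepted when the
    metabolite is known to the network at all; score 2 rows only when the
    metabolite participates in located metabolic reactions in **both**
    compartments; lower scores are rejected. The presence test runs against
    metabolic reactions only, never against previously added transports.
    """
    accepted: list[TransportReaction] = []
    rejected: list[RejectedTransport] = []
    for row in reference:
        for code in (row.comp_from, row.comp_to):
            check_compartment(code)
            if code == "U":
                raise ValueError("transport endpoints cannot be uncertain")
        if row.comp_from == row.comp_to:
            rejected.append(RejectedTransport(row, "identical endpoints"))
            continue
        if row.transporter_annotation:
            source = "transporter-annotation"
            min_score_ok = True
        else:
            source = f"reference-score{row.score}"
            min_score_ok = row.score >= 2
        if not min_score_ok:
            rejected.append(
                RejectedTransport(row, f"confidence score {row.score} < 2")
            )
            continue
        present = network.metabolite_compartments(row.metabolite_id)
        if row.score >= 3 or row.transporter_annotation:
            if row.metabolite_id not in network.metabolites:
                rejected.append(
                    RejectedTransport(row, "metabolite unknown to the network")
                )
                continue
        else:  # score 2: both-compartments rule
            missing = {row.comp_from, row.comp_to} - present
            if missing:
                rejected.append(
                    RejectedTransport(
                        row,
                        "metabolite absent from " + ",".join(sorted(missing)),
                    )
                )
                continue
        accepted.append(
            TransportReaction(
                id=transport_id(row.metabolite_id, row.comp_from, row.comp_to),
                metabolite_id=row.metabolite_id,
                comp_from=row.comp_from,
                comp_to=row.comp_to,
                reversible=row.reversible,
                source=source,
                protein_ids=tuple(sorted(row.protein_ids)),
            )
        )
    return accepted, rejected


# ---------------------------------------------------------------------------
# Dead ends


@dataclass(frozen=True)
class DeadEnd:
    metabolite_id: str
    compartment: str
    mode: str


def find_dead_ends(
    network: Network,
    currency: Iterable[str] = DEFAULT_CURRENCY,
    sole_participant: bool = True,
    pathway: str | None = None,
) -> list[DeadEnd]:
    """Detect dead-end metabolites per compartment.

    Within each real compartment (restricted to one pathway's reactions
    when *pathway* is given) a main metabolite is a dead end when it is
    only produced (every appearance a product of irreversible reactions),
    only consumed (symmetric), or — with ``sole_participant`` — confined to
    exactly one reaction regardless of reversibility. Reversible reactions
    count as both producer and consumer; transports already added count as
    reversible participants at both endpoints. Currency metabolites are
    never reported.
    """
    currency = frozenset(currency)
    produced: dict[tuple[str, str], int] = {}
    consumed: dict[tuple[str, str], int] = {}
    participations: dict[tuple[str, str], int] = {}

    def tally(met: str, comp: str, is_sub: bool, is_prod: bool, reversible: bool):
        key = (met, comp)
        participations[key] = participations.get(key, 0) + 1
        if is_prod or reversible:
            produced[key] = produced.get(key, 0) + 1
        if is_sub or reversible:
            consumed[key] = consumed.get(key, 0) + 1

    if pathway is None:
        reactions = list(network.reactions.values())
    else:
        reactions = network.pathway_reactions(pathway)
    for rxn in reactions:
        for comp in rxn.locations:
            if comp == "U":
                continue
            for met in rxn.metabolite_ids - currency:
                tally(
                    met,
                    comp,
                    met in rxn.substrate_ids,
                    met in rxn.product_ids,
                    rxn.reversible,
                )
    if pathway is None:
        for t in network.transports:
            if t.metabolite_id in currency:
                continue
            tally(t.metabolite_id, t.comp_from, True, False, t.reversible)
            tally(t.metabolite_id, t.comp_to, False, True, t.reversible)

    out: list[DeadEnd] = []
    for key in sorted(participations):
        met, comp = key
        n_prod = produced.get(key, 0)
        n_cons = consumed.get(key, 0)
        if n_prod and not n_cons:
            out.append(DeadEnd(met, comp, MODE_ONLY_PRODUCED))
        elif n_cons and not n_prod:
            out.append(DeadEnd(met, comp, MODE_ONLY_CONSUMED))
        elif sole_participant and participations[key] == 1:
            out.append(DeadEnd(met, comp, MODE_SOLE_PARTICIPANT))
    return out


def find_dead_ends_per_pathway(
    network: Network,
    currency: Iterable[str] = DEFAULT_CURRENCY,
    sole_participant: bool = True,
) -> dict[str, list[DeadEnd]]:
    """Per-pathway dead-end scan (the stricter phrasing of the analysis);
    shared metabolites may be flagged in several pathways."""
    return {
        pw: find_dead_ends(network, currency, sole_participant, pathway=pw)
        for pw in network.analysis_pathways()
    }


def infer_transports(
    network: Network,
    dead_ends: Iterable[DeadEnd],
    existing: Iterable[TransportReaction] = (),
) -> list[TransportReaction]:
    """Bridge multi-compartment dead-end metabolites through the cytosol.

    For each dead-end metabolite present (in located metabolic reactions)
    in a compartment set ``S`` with ``|S| >= 2``, reversible transports
    ``C <-> L`` are added for every other compartment ``L`` of ``S`` — the
    cytosol acts as hub, so every compartment holding the metabolite ends
    up linked and no such dead end survives re-analysis. Metabolites found
    nowhere else produce nothing (logged). Results are deduplicated against
    *existing* transports and among themselves.
    """
    seen: set[tuple[str, frozenset[str]]] = {
        (t.metabolite_id, t.pair) for t in existing
    }
    new: list[TransportReaction] = []
    for met in sorted({d.metabolite_id for d in dead_ends}):
        present = network.metabolite_compartments(met)
        if len(present) < 2:
            logger.info(
                "dead-end metabolite %s exists only in %s; no transport inferred",
                met,
                ",".join(sorted(present)) or "nowhere",
            )
            continue
        for other in sorted(present - {"C"}):
            key = (met, frozenset(("C", other)))
            if key in seen:
                continue
            seen.add(key)
            new.append(
                TransportReaction(
                    id=transport_id(met, "C", other),
                    metabolite_id=met,
                    comp_from="C",
                    comp_to=other,
                    reversible=True,
                    source="dead-end-inferred",
                )
            )
    return new


def dedup_transports(
    transports: Iterable[TransportReaction],
) -> tuple[list[TransportReaction], int]:
    """Collapse to one transport per (metabolite, unordered pair).

    Precedence by evidence class: direct reference evidence, then
    physiological reference evidence, then transporter annotation, then
    dead-end inference. Returns the canonical list (deterministically
    sorted) and the number of duplicates dropped.
    """
    rank = {source: i for i, source in enumerate(TRANSPORT_SOURCES)}
    best: dict[tuple[str, frozenset[str]], TransportReaction] = {}
    duplicates = 0
    for t in transports:
        key = (t.metabolite_id, t.pair)
        current = best.get(key)
        if current is None:
            best[key] = t
        else:
            duplicates += 1
            if rank.get(t.source, len(rank)) < rank.get(current.source, len(rank)):
                best[key] = t
    canonical = sorted(
        best.values(), key=lambda t: (t.metabolite_id, sorted(t.pair))
    )
    return canonical, duplicates
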