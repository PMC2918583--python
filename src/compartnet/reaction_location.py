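"""Reaction localization from protein locations, and the protein-reaction-
location relationship types.

A reaction inherits the union of its (active) catalysing proteins'
compartments. Reactions with no enzyme, or whose enzymes are all of unknown
location, default to ``U``. Each linked reaction is then classified:

* type ``a`` — one informative protein;
* type ``b`` — several proteins, all with identical location sets;
* type ``c`` — several proteins whose location sets are pairwise disjoint
  ("complementary proteins": each group of proteins serves the reaction in
  a different compartment, and usually only one group's annotation is
  biochemically right);
* type ``d`` — the residual mixed case: some locations shared, some unique.

Proteins whose only location is ``U`` carry no information and are excluded
from classification (they still contribute ``U`` when alone).

Type-c groups drive curation: an externally supplied verdict compartment
(literature evidence) deactivates the links of every complementary part
that does not contain the verdict, and the affected reactions are
re-localized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

from .model import (
    PROV_CURATED,
    PROV_DEFAULT_UNCERTAIN,
    PROV_PROTEIN,
    Network,
    Reaction,
)

logger = logging.getLogger(__name__)

#: Classification codes; ``unknown`` covers linked reactions whose proteins
#: are all of uncertain location.
TYPE_A, TYPE_B, TYPE_C, TYPE_D, TYPE_UNKNOWN = "a", "b", "c", "d", "unknown"


def assign_locations(network: Network, reaction: Reaction) -> dict[str, str]:
    """Compute one reaction's location set from its active proteins.

    Returns (and installs) a mapping compartment code -> provenance: the
    union of the catalysing proteins' compartments tagged ``protein``, with
    ``U`` dropped when any real compartment is present; ``{U}`` tagged
    ``default-uncertain`` for non-enzymatic or all-uncertain reactions.
    """
    codes: set[str] = set()
    for link in network.links_for_reaction(reaction.id):
        protein = network.proteins[link.protein_id]
        codes |= protein.location_codes
    real = codes - {"U"}
    if real:
        reaction.locations = {c: PROV_PROTEIN for c in real}
    else:
        reaction.locations = {"U": PROV_DEFAULT_UNCERTAIN}
    return reaction.locations


def localize_reactions(network: Network) -> None:
    """Assign every reaction's locations from the current protein locations
    and mark the network as localized."""
    for reaction in network.reactions.values():
        assign_locations(network, reaction)
    network.localized = True


def recompute_locations(network: Network, reaction: Reaction) -> dict[str, str]:
    """Refresh the protein-derived part of a reaction's location set.

    Locations with non-protein provenance (gap-filled, curated,
    cytosol-default) are preserved; protein-derived ones are rebuilt from
    the currently active links. An emptied set reverts to ``{U}``.
    """
    kept = {
        c: p
        for c, p in reaction.locations.items()
        if p not in (PROV_PROTEIN, PROV_DEFAULT_UNCERTAIN)
    }
    codes: set[str] = set()
    for link in network.links_for_reaction(reaction.id):
        codes |= network.proteins[link.protein_id].location_codes
    for c in codes - {"U"}:
        kept.setdefault(c, PROV_PROTEIN)
    if not kept:
        kept = {"U": PROV_DEFAULT_UNCERTAIN}
        logger.info("reaction %s reverted to uncertain location", reaction.id)
    reaction.locations = kept
    return kept


def _informative_proteins(network: Network, reaction_id: str) -> dict[str, frozenset[str]]:
    """Active proteins of a reaction with at least one real compartment."""
    out: dict[str, frozenset[str]] = {}
    for link in network.links_for_reaction(reaction_id):
        protein = network.proteins[link.protein_id]
        real = frozenset(protein.real_location_codes)
        if real:
            out[protein.id] = real
    return out


def classify(network: Network, reaction_id: str) -> str | None:
    """Classify a reaction's protein-reaction-location relationship.

    Returns one of ``a``/``b``/``c``/``d``/``unknown``; ``None`` for
    reactions with no active protein link (unclassified non-enzymatic
    reactions). Invariant under protein order.
    """
    links = network.links_for_reaction(reaction_id)
    if not links:
        return None
    informative = _informative_proteins(network, reaction_id)
    if not informative:
        return TYPE_UNKNOWN
    location_sets = list(informative.values())
    if len(informative) == 1:
        return TYPE_A
    distinct = set(location_sets)
    if len(distinct) == 1:
        return TYPE_B
    if all(a.isdisjoint(b) for a, b in combinations(distinct, 2)):
        return TYPE_C
    return TYPE_D


def classify_all(network: Network) -> dict[str, str | None]:
    """Classify every reaction; keys are reaction ids."""
    return {rid: classify(network, rid) for rid in sorted(network.reactions)}


@dataclass
class ComplementaryGroup:
    """Type-c structure: a protein partition with pairwise disjoint location
    sets, shared by one or more reactions."""

    parts: tuple[tuple[frozenset[str], frozenset[str]], ...]  # (proteins, locations)
    reaction_ids: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple:
        return self.parts

    @property
    def all_locations(self) -> set[str]:
        out: set[str] = set()
        for _proteins, locs in self.parts:
            out |= locs
        return out

    def proteins_outside(self, compartment: str) -> set[str]:
        """Proteins of every part whose location set excludes *compartment*."""
        out: set[str] = set()
        for proteins, locs in self.parts:
            if compartment not in locs:
                out |= proteins
        return out


def _partition_key(informative: dict[str, frozenset[str]]) -> tuple:
    """Canonical partition of proteins by identical location set."""
    by_locs: dict[frozenset[str], set[str]] = {}
    for pid, locs in informative.items():
        by_locs.setdefault(locs, set()).add(pid)
    parts = [(frozenset(pids), locs) for locs, pids in by_locs.items()]
    parts.sort(key=lambda part: (sorted(part[1]), sorted(part[0])))
    return tuple(parts)


def find_complementary_groups(network: Network) -> list[ComplementaryGroup]:
    """Aggregate type-c reactions sharing the same protein partition.

    Each group lists every reaction it covers; groups are returned in a
    deterministic order (by smallest reaction id).
    """
    groups: dict[tuple, ComplementaryGroup] = {}
    for rid in sorted(network.reactions):
        if classify(network, rid) != TYPE_C:
            continue
        key = _partition_key(_informative_proteins(network, rid))
        group = groups.setdefault(key, ComplementaryGroup(parts=key))
        group.reaction_ids.add(rid)
    return sorted(groups.values(), key=lambda g: min(g.reaction_ids))


@dataclass
class LinkDeletion:
    protein_id: str
    reaction_id: str
    reason: str


def resolve_type_c(
    network: Network,
    group: ComplementaryGroup,
    verdict: str,
    citation: str = "",
) -> list[LinkDeletion]:
    """Apply a literature verdict to a complementary group.

    The verdict names the compartment in which the group's reactions really
    occur. Links of proteins in parts whose location set excludes the
    verdict are deactivated for the group's reactions, and each reaction's
    locations are recomputed with the verdict tagged ``curated``.
    """
    if verdict not in group.all_locations:
        raise ValueError(
            f"verdict {verdict!r} not among the group's part locations "
            f"{sorted(group.all_locations)}"
        )
    wrong = group.proteins_outside(verdict)
    deletions: list[LinkDeletion] = []
    for rid in sorted(group.reaction_ids):
        for pid in sorted(wrong):
            link = network.get_link(pid, rid)
            if link is not None and link.active:
                link.active = False
                link.note = f"type-c revision: reaction occurs in {verdict}"
                deletions.append(
                    LinkDeletion(pid, rid, f"complementary-group verdict {verdict}")
                )
        reaction = network.reactions[rid]
        recompute_locations(network, reaction)
        # drop any stale protein-derived tag for the verdict, then mark it
        reaction.locations = {
            c: p for c, p in reaction.locations.items() if c != "U"
        }
        reaction.set_location(verdict, PROV_CURATED)
        if citation:
            pass  # citation travels with the deletions report, not the model
    return deletions
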