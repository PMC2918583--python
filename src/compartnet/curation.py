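"""Declarative, citation-bearing curation edits with an audit trail.

Literature-based revision (e.g. relocating beta-oxidation reactions by
chain length, or deleting protein-reaction links contradicted by enzyme
function) is expressed as data: ordered edit records applied atomically by
:func:`apply_edits`. The biology lives in the edit files; the module only
implements the machinery, so a revision is replayable and auditable.

:func:`check_rules` is an advisory checker for location heuristics of the
"reactions coupled with H2O2 belong in peroxisomes" kind — it reports
violations and never edits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model import PROV_CURATED, Network, check_compartment
from .reaction_location import recompute_locations

logger = logging.getLogger(__name__)

KIND_DELETE_LINK = "delete-link"
KIND_ADD_LINK = "add-link"
KIND_SET_LOCATIONS = "set-locations"
KIND_ADD_LOCATION = "add-location"
KIND_REMOVE_LOCATION = "remove-location"

EDIT_KINDS = (
    KIND_DELETE_LINK,
    KIND_ADD_LINK,
    KIND_SET_LOCATIONS,
    KIND_ADD_LOCATION,
    KIND_REMOVE_LOCATION,
)


@dataclass
class CurationEdit:
    order: int
    kind: str
    reaction_id: str
    protein_id: str = ""
    compartments: tuple[str, ...] = ()
    citation: str = ""


@dataclass
class AuditEntry:
    edit: CurationEdit
    accepted: bool
    before: str
    after: str
    message: str = ""


def _reaction_state(network: Network, reaction_id: str) -> str:
    rxn = network.reactions.get(reaction_id)
    if rxn is None:
        return "<missing>"
    locs = ",".join(f"{c}:{p}" for c, p in sorted(rxn.locations.items()))
    links = ",".join(
        f"{l.protein_id}{'' if l.active else '!'}"
        for l in sorted(
            network.links_for_reaction(reaction_id, active_only=False),
            key=lambda l: l.protein_id,
        )
    )
    return f"locations[{locs}] links[{links}]"


def apply_edits(
    network: Network,
    edits: Iterable[CurationEdit],
    strict: bool = False,
) -> list[AuditEntry]:
    """Apply edits in order-index sequence; return the audit log.

    ``delete-link`` soft-deactivates and re-localizes the reaction;
    ``set-locations`` replaces the whole location set (provenance
    ``curated``); ``add-location``/``remove-location`` adjust single
    compartments. An edit referencing a missing entity is rejected and
    logged (or aborts everything in strict mode); a ``remove-location``
    that would empty a reaction reverts it to ``U`` via re-localization
    rules is not attempted — the edit is rejected instead.
    """
    log: list[AuditEntry] = []
    for edit in sorted(edits, key=lambda e: e.order):
        before = _reaction_state(network, edit.reaction_id)
        try:
            _apply_one(network, edit)
        except (KeyError, ValueError) as exc:
            if strict:
                raise
            logger.warning("edit %d rejected: %s", edit.order, exc)
            log.append(AuditEntry(edit, False, before, before, str(exc)))
            continue
        after = _reaction_state(network, edit.reaction_id)
        log.append(AuditEntry(edit, True, before, after))
    return log


def _apply_one(network: Network, edit: CurationEdit) -> None:
    if edit.kind not in EDIT_KINDS:
        raise ValueError(f"unknown edit kind {edit.kind!r}")
    rxn = network.reactions.get(edit.reaction_id)
    if rxn is None:
        raise KeyError(f"unknown reaction {edit.reaction_id!r}")
    for code in edit.compartments:
        check_compartment(code)

    if edit.kind == KIND_DELETE_LINK:
        link = network.get_link(edit.protein_id, edit.reaction_id)
        if link is None:
            raise KeyError(
                f"unknown link ({edit.protein_id}, {edit.reaction_id})"
            )
        link.active = False
        link.note = f"curation: {edit.citation}" if edit.citation else "curation"
        recompute_locations(network, rxn)
    elif edit.kind == KIND_ADD_LINK:
        if edit.protein_id not in network.proteins:
            raise KeyError(f"unknown protein {edit.protein_id!r}")
        link = network.get_link(edit.protein_id, edit.reaction_id)
        if link is None:
            network.add_link(edit.protein_id, edit.reaction_id)
        else:
            link.active = True
        recompute_locations(network, rxn)
    elif edit.kind == KIND_SET_LOCATIONS:
        if not edit.compartments:
            raise ValueError("set-locations requires a non-empty payload")
        rxn.locations = {c: PROV_CURATED for c in edit.compartments}
    elif edit.kind == KIND_ADD_LOCATION:
        if len(edit.compartments) != 1:
            raise ValueError("add-location takes exactly one compartment")
        rxn.set_location(edit.compartments[0], PROV_CURATED)
    elif edit.kind == KIND_REMOVE_LOCATION:
        if len(edit.compartments) != 1:
            raise ValueError("remove-location takes exactly one compartment")
        code = edit.compartments[0]
        if code not in rxn.locations:
            raise KeyError(
                f"reaction {edit.reaction_id} not located in {code}"
            )
        if set(rxn.locations) == {code}:
            raise ValueError(
                f"removing {code} would leave reaction {edit.reaction_id} "
                "without locations"
            )
        rxn.drop_location(code)


# ---------------------------------------------------------------------------
# Advisory rules


@dataclass
class LocationRule:
    """Reactions touching *metabolite_id* should include *compartment*."""

    metabolite_id: str
    compartment: str
    description: str = ""


@dataclass
class ChainLengthRule:
    """Reactions consuming an acyl chain longer than *carbon_threshold*
    carbons should include *compartment* (very-long-chain oxidation is
    peroxisomal)."""

    carbon_threshold: int
    compartment: str
    description: str = ""


@dataclass
class RuleViolation:
    reaction_id: str
    rule: str
    suggested_compartment: str


def check_rules(
    network: Network,
    location_rules: Iterable[LocationRule] = (),
    chain_rules: Iterable[ChainLengthRule] = (),
    carbon_counts: Mapping[str, int] | None = None,
) -> list[RuleViolation]:
    """Report located reactions violating advisory location heuristics.

    *carbon_counts* maps metabolite ids to their carbon number and must be
    supplied for chain-length rules (carbon counts are input data, never
    inferred from names). Purely advisory: no edits are made.
    """
    carbon_counts = dict(carbon_counts or {})
    violations: list[RuleViolation] = []
    for rxn in sorted(network.reactions.values(), key=lambda r: r.id):
        locs = set(rxn.locations) - {"U"}
        if not locs:
            continue
        for rule in location_rules:
            if rule.metabolite_id in rxn.metabolite_ids and rule.compartment not in locs:
                violations.append(
                    RuleViolation(
                        rxn.id,
                        rule.description
                        or f"reactions with {rule.metabolite_id} belong in {rule.compartment}",
                        rule.compartment,
                    )
                )
        for chain_rule in chain_rules:
            long_chain = any(
                carbon_counts.get(m, 0) > chain_rule.carbon_threshold
                for m in rxn.substrate_ids
            )
            if long_chain and chain_rule.compartment not in locs:
                violations.append(
                    RuleViolation(
                        rxn.id,
                        chain_rule.description
                        or f"chains > C{chain_rule.carbon_threshold} belong in "
                        f"{chain_rule.compartment}",
                        chain_rule.compartment,
                    )
                )
    return violations
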