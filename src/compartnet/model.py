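"""In-memory model of a compartmentalized metabolic network.

The central object is :class:`Network`: metabolites, reactions, proteins,
protein-reaction links and a pathway index. Every pipeline stage (protein
localization, reaction localization, type-c revision, gap filling, IRLR
revision, curation, transport inference) transforms a ``Network`` in place
and records provenance for each location it touches, so a finished network
carries a full audit trail of why each reaction sits where it does.

Eight sub-cellular compartments are modelled (extracellular, nucleus,
cytosol, endoplasmic reticulum, Golgi apparatus, peroxisome, lysosome,
mitochondrion) plus the placeholder ``U`` ("uncertain") used for proteins
and reactions whose location is unknown. ``U`` is never a target of any
structural analysis.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

# ---------------------------------------------------------------------------
# Compartments

#: Location-provenance tags, in pipeline order of precedence of appearance.
PROV_PROTEIN = "protein"
PROV_DEFAULT_UNCERTAIN = "default-uncertain"
PROV_GAP_FILLED = "gap-filled"
PROV_CURATED = "curated"
PROV_CYTOSOL_DEFAULT = "cytosol-default"

PROVENANCES = frozenset(
    {
        PROV_PROTEIN,
        PROV_DEFAULT_UNCERTAIN,
        PROV_GAP_FILLED,
        PROV_CURATED,
        PROV_CYTOSOL_DEFAULT,
    }
)

#: Protein-location sources.
SOURCE_GO = "GO"
SOURCE_KEYWORD = "keyword"


@dataclass(frozen=True)
class Compartment:
    """A sub-cellular location code and its ontology anchor term.

    ``U`` (uncertain) is a placeholder with no ontology term; the eight real
    codes map one-to-one onto cellular-component terms.
    """

    code: str
    go_id: str
    name: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


#: The nine compartment codes. GO anchors are the standard cellular-component
#: terms for the eight physical locations.
COMPARTMENTS: dict[str, Compartment] = {
    c.code: c
    for c in (
        Compartment("E", "GO:0005576", "extracellular region"),
        Compartment("U", "", "uncertain"),
        Compartment("N", "GO:0005634", "nucleus"),
        Compartment("C", "GO:0005829", "cytosol"),
        Compartment("ER", "GO:0005783", "endoplasmic reticulum"),
        Compartment("GA", "GO:0005794", "Golgi apparatus"),
        Compartment("X", "GO:0005777", "peroxisome"),
        Compartment("L", "GO:0005764", "lysosome"),
        Compartment("M", "GO:0005739", "mitochondrion"),
    )
}

#: The eight physical compartments (everything but ``U``), in canonical order.
REAL_COMPARTMENTS: tuple[str, ...] = ("E", "N", "C", "ER", "GA", "X", "L", "M")

#: Canonical order including the uncertain placeholder.
ALL_COMPARTMENTS: tuple[str, ...] = ("E", "U", "N", "C", "ER", "GA", "X", "L", "M")

#: Default mapping ontology term -> compartment code for backtracking. The
#: plasma-membrane term is an extra entry resolving to cytosol: membrane
#: proteins overwhelmingly catalyse cytosolic chemistry.
PLASMA_MEMBRANE_GO = "GO:0005886"

DEFAULT_TARGET_MAP: dict[str, str] = {
    **{COMPARTMENTS[c].go_id: c for c in REAL_COMPARTMENTS},
    PLASMA_MEMBRANE_GO: "C",
}

#: Name of the catch-all pathway excluded from all structural analyses.
ISOLATED_PATHWAY = "isolated"


def check_compartment(code: str) -> str:
    """Return *code* if it names a known compartment, else raise ValueError."""
    if code not in COMPARTMENTS:
        raise ValueError(f"unknown compartment code: {code!r}")
    return code


# ---------------------------------------------------------------------------
# Entities


@dataclass
class Metabolite:
    id: str
    name: str = ""


@dataclass
class Reaction:
    """A metabolic reaction with role-resolved participants.

    ``locations`` maps compartment code -> provenance tag. Stoichiometry is
    stored but the compartmentalization procedures are purely topological:
    only presence and role (substrate vs product) matter.
    """

    id: str
    substrates: list[tuple[str, float]] = field(default_factory=list)
    products: list[tuple[str, float]] = field(default_factory=list)
    reversible: bool = False
    pathways: set[str] = field(default_factory=set)
    ec: str = ""
    locations: dict[str, str] = field(default_factory=dict)

    # -- participant views -------------------------------------------------
    @property
    def substrate_ids(self) -> set[str]:
        return {m for m, _ in self.substrates}

    @property
    def product_ids(self) -> set[str]:
        return {m for m, _ in self.products}

    @property
    def metabolite_ids(self) -> set[str]:
        return self.substrate_ids | self.product_ids

    def main_metabolites(self, currency: frozenset[str] | set[str]) -> set[str]:
        """Participants that are not currency metabolites."""
        return self.metabolite_ids - set(currency)

    def producible(self) -> set[str]:
        """Metabolites this reaction can produce under a permitted direction."""
        return self.metabolite_ids if self.reversible else self.product_ids

    def consumable(self) -> set[str]:
        """Metabolites this reaction can consume under a permitted direction."""
        return self.metabolite_ids if self.reversible else self.substrate_ids

    # -- location editing --------------------------------------------------
    @property
    def location_codes(self) -> set[str]:
        return set(self.locations)

    def set_location(self, code: str, provenance: str) -> None:
        check_compartment(code)
        if provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance: {provenance!r}")
        self.locations[code] = provenance

    def drop_location(self, code: str) -> None:
        self.locations.pop(code, None)


@dataclass
class Protein:
    """An enzyme with its resolved compartments.

    ``locations`` maps compartment code -> set of sources ({"GO","keyword"}).
    A protein with no resolvable annotation carries ``{U}``.
    """

    id: str
    locations: dict[str, set[str]] = field(default_factory=dict)

    @property
    def location_codes(self) -> set[str]:
        return set(self.locations)

    @property
    def real_location_codes(self) -> set[str]:
        return {c for c in self.locations if c != "U"}

    def add_location(self, code: str, source: str) -> None:
        check_compartment(code)
        self.locations.setdefault(code, set()).add(source)


@dataclass
class ProteinReactionLink:
    """A protein-reaction (GPR) association; deletions are soft."""

    protein_id: str
    reaction_id: str
    active: bool = True
    note: str = ""


@dataclass
class TransportReaction:
    """A pseudo-reaction moving one metabolite between two compartments."""

    id: str
    metabolite_id: str
    comp_from: str
    comp_to: str
    reversible: bool = True
    source: str = "dead-end-inferred"
    protein_ids: tuple[str, ...] = ()

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.comp_from, self.comp_to))


#: Transport source classes, in deduplication precedence order (best first).
TRANSPORT_SOURCES: tuple[str, ...] = (
    "reference-score3",
    "reference-score2",
    "transporter-annotation",
    "dead-end-inferred",
)


# ---------------------------------------------------------------------------
# Network container


class Network:
    """Mutable container tying reactions, metabolites, proteins and links.

    The pathway index is maintained incrementally by :meth:`add_reaction`;
    call :meth:`rebuild_pathway_index` after editing ``Reaction.pathways``
    directly.
    """

    def __init__(self) -> None:
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.proteins: dict[str, Protein] = {}
        self.links: list[ProteinReactionLink] = []
        self.transports: list[TransportReaction] = []
        self.pathway_index: dict[str, set[str]] = {}
        #: set once reaction localization has run; validate() then requires
        #: every reaction to carry at least one location.
        self.localized: bool = False

    # -- construction ------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        existing = self.metabolites.get(met.id)
        if existing is not None:
            return existing
        self.metabolites[met.id] = met
        return met

    def ensure_metabolite(self, met_id: str) -> Metabolite:
        return self.add_metabolite(Metabolite(met_id, met_id))

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id: {rxn.id}")
        self.reactions[rxn.id] = rxn
        for met_id in rxn.metabolite_ids:
            self.ensure_metabolite(met_id)
        for pw in rxn.pathways:
            self.pathway_index.setdefault(pw, set()).add(rxn.id)
        return rxn

    def add_protein(self, protein: Protein) -> Protein:
        existing = self.proteins.get(protein.id)
        if existing is not None:
            return existing
        self.proteins[protein.id] = protein
        return protein

    def add_link(self, protein_id: str, reaction_id: str, active: bool = True) -> ProteinReactionLink:
        for link in self.links:
            if link.protein_id == protein_id and link.reaction_id == reaction_id:
                raise ValueError(f"duplicate link: ({protein_id}, {reaction_id})")
        link = ProteinReactionLink(protein_id, reaction_id, active)
        self.links.append(link)
        return link

    def rebuild_pathway_index(self) -> None:
        self.pathway_index = {}
        for rxn in self.reactions.values():
            for pw in rxn.pathways:
                self.pathway_index.setdefault(pw, set()).add(rxn.id)

    # -- queries -----------------------------------------------------------
    def links_for_reaction(self, reaction_id: str, active_only: bool = True) -> list[ProteinReactionLink]:
        return [
            l
            for l in self.links
            if l.reaction_id == reaction_id and (l.active or not active_only)
        ]

    def links_for_protein(self, protein_id: str, active_only: bool = True) -> list[ProteinReactionLink]:
        return [
            l
            for l in self.links
            if l.protein_id == protein_id and (l.active or not active_only)
        ]

    def get_link(self, protein_id: str, reaction_id: str) -> Optional[ProteinReactionLink]:
        for l in self.links:
            if l.protein_id == protein_id and l.reaction_id == reaction_id:
                return l
        return None

    def analysis_pathways(self) -> list[str]:
        """Pathway names subject to structural analysis (sorted, minus the
        catch-all "isolated" pathway)."""
        return sorted(p for p in self.pathway_index if p != ISOLATED_PATHWAY)

    def pathway_reactions(self, pathway: str) -> list[Reaction]:
        if pathway not in self.pathway_index:
            raise KeyError(f"unknown pathway: {pathway!r}")
        return [self.reactions[r] for r in sorted(self.pathway_index[pathway])]

    def reactions_in(self, compartment: str) -> Iterator[Reaction]:
        check_compartment(compartment)
        for rxn in self.reactions.values():
            if compartment in rxn.locations:
                yield rxn

    def metabolite_compartments(self, met_id: str, include_transports: bool = False) -> set[str]:
        """Compartments in which *met_id* participates in located reactions.

        ``U`` is excluded. With ``include_transports`` the endpoints of
        transport reactions count as presence too.
        """
        comps: set[str] = set()
        for rxn in self.reactions.values():
            if met_id in rxn.metabolite_ids:
                comps |= {c for c in rxn.locations if c != "U"}
        if include_transports:
            for t in self.transports:
                if t.metabolite_id == met_id:
                    comps |= {t.comp_from, t.comp_to}
        return comps

    def copy(self) -> "Network":
        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Validation


def validate(network: Network) -> list[str]:
    """Check the model invariants; return human-readable violations.

    Reporting only — never mutates the network, and repeated calls return
    the same list.
    """
    violations: list[str] = []

    for rxn in network.reactions.values():
        if not rxn.substrates:
            violations.append(f"reaction {rxn.id}: empty substrate list")
        if not rxn.products:
            violations.append(f"reaction {rxn.id}: empty product list")
        for met_id in rxn.metabolite_ids:
            if met_id not in network.metabolites:
                violations.append(
                    f"reaction {rxn.id}: unknown metabolite {met_id!r}"
                )
        for code, prov in rxn.locations.items():
            if code not in COMPARTMENTS:
                violations.append(
                    f"reaction {rxn.id}: unknown compartment code {code!r}"
                )
            if prov not in PROVENANCES:
                violations.append(
                    f"reaction {rxn.id}: unknown provenance {prov!r} for {code}"
                )
        if network.localized and not rxn.locations:
            violations.append(
                f"reaction {rxn.id}: no location after localization stage"
            )

    for protein in network.proteins.values():
        for code in protein.locations:
            if code not in COMPARTMENTS:
                violations.append(
                    f"protein {protein.id}: unknown compartment code {code!r}"
                )

    seen_pairs: set[tuple[str, str]] = set()
    for link in network.links:
        pair = (link.protein_id, link.reaction_id)
        if pair in seen_pairs:
            violations.append(f"duplicate link: {pair}")
        seen_pairs.add(pair)
        if link.reaction_id not in network.reactions:
            violations.append(
                f"link ({link.protein_id}, {link.reaction_id}): unknown reaction "
                f"{link.reaction_id!r}"
            )
        if link.protein_id not in network.proteins:
            violations.append(
                f"link ({link.protein_id}, {link.reaction_id}): unknown protein "
                f"{link.protein_id!r}"
            )

    for pw, rids in network.pathway_index.items():
        for rid in rids:
            if rid not in network.reactions:
                violations.append(f"pathway {pw!r}: unknown reaction {rid!r}")
            elif pw not in network.reactions[rid].pathways:
                violations.append(
                    f"pathway index inconsistent: {rid} not tagged with {pw!r}"
                )

    for t in network.transports:
        if t.comp_from == t.comp_to:
            violations.append(f"transport {t.id}: identical endpoints")
        for code in (t.comp_from, t.comp_to):
            if code not in COMPARTMENTS or code == "U":
                violations.append(
                    f"transport {t.id}: invalid compartment {code!r}"
                )
        if t.metabolite_id not in network.metabolites:
            violations.append(
                f"transport {t.id}: unknown metabolite {t.metabolite_id!r}"
            )

    return violations
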