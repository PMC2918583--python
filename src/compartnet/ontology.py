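"""Cellular-component ontology parsing and protein localization.

Proteins are annotated to arbitrary ontology terms ("mitochondrial
membrane", "nuclear envelope", ...). To place them into the eight modelled
compartments, each annotated term is *backtracked*: the ontology DAG is
ascended along ``is_a`` and ``part_of`` edges until a term of the target map
(the eight anchor terms of :data:`compartnet.model.DEFAULT_TARGET_MAP`,
plus plasma membrane which resolves to cytosol) is reached. A term whose
ancestry never meets a target resolves to ``U`` (uncertain).

GO-derived compartments are merged with keyword-derived compartments
(e.g. a curated location-keyword table); a protein with conflicting sources
is assigned to all locations, and ``U`` is dropped as soon as any real
compartment is known from either source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import obonet

from .model import DEFAULT_TARGET_MAP, Network, check_compartment

logger = logging.getLogger(__name__)

#: Ontology relations followed when ascending toward the anchor terms.
#: ``part_of`` is required for membrane -> organelle ancestry; regulatory
#: relations are deliberately ignored.
TRAVERSAL_RELATIONS = frozenset({"is_a", "part_of"})

#: Default mapping of location keywords (curated-database style) to
#: compartment codes. Six organelle keywords; extracellular/cytosol style
#: keywords are intentionally absent from the default map.
DEFAULT_KEYWORD_MAP: dict[str, str] = {
    "nucleus": "N",
    "endoplasmic reticulum": "ER",
    "golgi apparatus": "GA",
    "peroxisome": "X",
    "lysosome": "L",
    "mitochondrion": "M",
}


class OntologyParseError(ValueError):
    """Raised when an OBO stream cannot be parsed."""


def resolve_keywords(
    pairs: Iterable[tuple[str, str]],
    keyword_map: Mapping[str, str] | None = None,
) -> list[tuple[str, str]]:
    """Map (protein, keyword) rows to (protein, compartment-code) rows.

    Unknown keywords are logged and skipped; matching is case-insensitive.
    """
    keyword_map = {k.lower(): v for k, v in (keyword_map or DEFAULT_KEYWORD_MAP).items()}
    out = []
    for protein_id, keyword in pairs:
        code = keyword_map.get(keyword.strip().lower())
        if code is None:
            logger.warning("unknown location keyword %r skipped", keyword)
            continue
        out.append((protein_id, code))
    return out


@dataclass
class OntologyTerm:
    id: str
    name: str = ""
    parents: set[tuple[str, str]] = field(default_factory=set)
    obsolete: bool = False


class Ontology:
    """A parsed ontology restricted to ``is_a``/``part_of`` ancestry."""

    def __init__(self, terms: Mapping[str, OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = dict(terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from *term_id* by ascending edges, the term
        itself included. Obsolete terms neither appear nor are traversed."""
        if term_id not in self.terms:
            raise KeyError(f"unknown ontology term: {term_id!r}")
        seen: set[str] = set()
        stack = [term_id]
        while stack:
            current = stack.pop()
            if current in seen:
                continue
            term = self.terms.get(current)
            if term is None or term.obsolete:
                continue
            seen.add(current)
            for parent_id, relation in term.parents:
                if relation in TRAVERSAL_RELATIONS:
                    stack.append(parent_id)
        return seen

    def check_edges(self) -> list[str]:
        """Report parent references that do not resolve within the ontology."""
        problems = []
        for term in self.terms.values():
            for parent_id, _rel in term.parents:
                if parent_id not in self.terms:
                    problems.append(
                        f"term {term.id}: unresolved parent {parent_id!r}"
                    )
        return problems


def parse_ontology(source) -> Ontology:
    """Parse an OBO 1.2/1.4 stream or path into an :class:`Ontology`.

    Only ``[Term]`` stanzas are consumed; ``is_a`` and
    ``relationship: part_of`` lines become parent edges. Obsolete terms are
    kept but flagged, so backtracking never traverses them.
    """
    try:
        graph = obonet.read_obo(source, ignore_obsolete=False)
    except Exception as exc:  # malformed stanza, bad header, ...
        raise OntologyParseError(f"cannot parse OBO source: {exc}") from exc

    terms: dict[str, OntologyTerm] = {}
    for term_id, data in graph.nodes(data=True):
        parents: set[tuple[str, str]] = set()
        for parent_id in data.get("is_a", []):
            parents.add((parent_id, "is_a"))
        for rel in data.get("relationship", []):
            # "part_of GO:0005739" style payloads
            parts = rel.split()
            if len(parts) == 2:
                parents.add((parts[1], parts[0]))
        terms[term_id] = OntologyTerm(
            id=term_id,
            name=data.get("name", ""),
            parents=parents,
            obsolete=bool(data.get("is_obsolete", False)),
        )
    return Ontology(terms)


@dataclass
class LocationAssignment:
    """Resolved compartments of one protein, with per-compartment sources."""

    protein_id: str
    compartments: set[str] = field(default_factory=set)
    sources: dict[str, set[str]] = field(default_factory=dict)

    def add(self, code: str, source: str) -> None:
        check_compartment(code)
        self.compartments.add(code)
        self.sources.setdefault(code, set()).add(source)

    def drop_uncertain_if_real(self) -> None:
        real = self.compartments - {"U"}
        if real:
            self.compartments = real
            self.sources.pop("U", None)


def backtrack(
    term_id: str,
    ontology: Ontology,
    target_map: Mapping[str, str] | None = None,
) -> set[str]:
    """Resolve an ontology term to compartment codes by ancestor search.

    Every target compartment whose anchor term is an ancestor of *term_id*
    (reflexively) is returned; ``{"U"}`` if no anchor is reachable.
    """
    if target_map is None:
        target_map = DEFAULT_TARGET_MAP
    hits = {
        target_map[ancestor]
        for ancestor in ontology.ancestors(term_id)
        if ancestor in target_map
    }
    return hits or {"U"}


def localize_protein(
    protein_id: str,
    annotations: Iterable[str],
    keyword_locations: Iterable[str],
    ontology: Ontology,
    target_map: Mapping[str, str] | None = None,
) -> LocationAssignment:
    """Merge GO-backtracked and keyword compartments for one protein.

    ``U`` is dropped whenever at least one real compartment is known from
    either source; a protein with no resolvable information gets ``{U}``.
    Annotation terms missing from the ontology are skipped with a warning.
    """
    assignment = LocationAssignment(protein_id)
    for term_id in annotations:
        if term_id not in ontology:
            logger.warning(
                "protein %s: unknown ontology term %s skipped", protein_id, term_id
            )
            continue
        for code in backtrack(term_id, ontology, target_map):
            assignment.add(code, "GO")
    for code in keyword_locations:
        assignment.add(check_compartment(code), "keyword")
    assignment.drop_uncertain_if_real()
    if not assignment.compartments:
        assignment.add("U", "GO")
    return assignment


def localize_all(
    associations: Iterable[tuple[str, str]],
    keywords: Iterable[tuple[str, str]],
    ontology: Ontology,
    target_map: Mapping[str, str] | None = None,
) -> tuple[dict[str, LocationAssignment], dict[str, int]]:
    """Localize every protein mentioned in either table.

    *associations* yields ``(protein_id, term_id)`` pairs, *keywords* yields
    ``(protein_id, compartment_code)`` pairs (keywords pre-resolved to codes
    by the reader). Returns the assignments and a per-compartment summary in
    which a multi-location protein is counted once per compartment it holds.
    """
    terms_by_protein: dict[str, set[str]] = {}
    for protein_id, term_id in associations:
        terms_by_protein.setdefault(protein_id, set()).add(term_id)
    codes_by_protein: dict[str, set[str]] = {}
    for protein_id, code in keywords:
        codes_by_protein.setdefault(protein_id, set()).add(code)

    assignments: dict[str, LocationAssignment] = {}
    for protein_id in sorted(set(terms_by_protein) | set(codes_by_protein)):
        assignments[protein_id] = localize_protein(
            protein_id,
            sorted(terms_by_protein.get(protein_id, ())),
            sorted(codes_by_protein.get(protein_id, ())),
            ontology,
            target_map,
        )

    counts: dict[str, int] = {}
    for assignment in assignments.values():
        for code in assignment.compartments:
            counts[code] = counts.get(code, 0) + 1
    return assignments, counts


def apply_assignments(
    network: Network, assignments: Mapping[str, LocationAssignment]
) -> None:
    """Write location assignments onto the network's proteins.

    Network proteins absent from *assignments* fall back to ``{U}``.
    """
    for protein in network.proteins.values():
        assignment = assignments.get(protein.id)
        protein.locations = {}
        if assignment is None:
            protein.add_location("U", "GO")
            continue
        for code in assignment.compartments:
            for source in assignment.sources.get(code, {"GO"}):
                protein.add_location(code, source)
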