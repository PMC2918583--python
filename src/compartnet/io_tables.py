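"""Readers and writers for the tabular dialects and model exports.

Everything is plain text: TSV tables for reactions, annotations, evidence
and reports; OBO for the ontology; YAML for run configuration; SBML Level 3
and Graphviz DOT as exports. Reaction equations use a compact string form::

    A + 2 B = C      (reversible)
    A + 2 B => C     (irreversible)

Writers emit deterministically sorted rows so that repeated runs are
byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .curation import AuditEntry, CurationEdit
from .gap_irlr import GapEvidence, GapRecord, IRLREvidence, IRLRRecord
from .model import (
    ALL_COMPARTMENTS,
    Metabolite,
    Network,
    Protein,
    ProteinReactionLink,
    Reaction,
    TransportReaction,
    check_compartment,
)
from .ontology import DEFAULT_KEYWORD_MAP
from .transport import DeadEnd, ReferenceTransport, RejectedTransport

logger = logging.getLogger(__name__)

#: Species-id suffix per compartment in SBML export (genome-scale-model style).
SBML_SUFFIX = {
    "E": "e",
    "N": "n",
    "C": "c",
    "ER": "er",
    "GA": "ga",
    "X": "x",
    "L": "l",
    "M": "m",
}


class EquationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Equations


def parse_equation(equation: str) -> tuple[list[tuple[str, float]], list[tuple[str, float]], bool]:
    """Parse ``A + 2 B = C`` / ``A => B`` into (substrates, products,
    reversible)."""
    if " => " in equation:
        left, right = equation.split(" => ", 1)
        reversible = False
    elif " = " in equation:
        left, right = equation.split(" = ", 1)
        reversible = True
    else:
        raise EquationError(f"no ' = ' or ' => ' separator in {equation!r}")

    def parse_side(side: str, which: str) -> list[tuple[str, float]]:
        terms = []
        for raw in side.split(" + "):
            token = raw.strip()
            # catch dangling separators ("A + = B" leaves a bare "+")
            if not token or token == "+" or token.endswith(" +") or token.startswith("+ "):
                raise EquationError(f"empty term on {which} side of {equation!r}")
            parts = token.split(None, 1)
            if len(parts) == 2 and parts[0].replace(".", "", 1).isdigit():
                coeff, met = float(parts[0]), parts[1]
            else:
                coeff, met = 1.0, token
            terms.append((met, coeff))
        return terms

    return parse_side(left, "substrate"), parse_side(right, "product"), reversible


def format_equation(reaction: Reaction) -> str:
    def fmt(terms: Sequence[tuple[str, float]]) -> str:
        out = []
        for met, coeff in terms:
            if coeff == 1:
                out.append(met)
            else:
                c = int(coeff) if float(coeff).is_integer() else coeff
                out.append(f"{c} {met}")
        return " + ".join(out)

    sep = " = " if reaction.reversible else " => "
    return fmt(reaction.substrates) + sep + fmt(reaction.products)


# ---------------------------------------------------------------------------
# Generic TSV helpers


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _write_rows(path: Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _split(field: str, sep: str = ";") -> list[str]:
    return [x for x in field.split(sep) if x]


# ---------------------------------------------------------------------------
# Network I/O


def read_network(
    reaction_table: str | Path, link_table: str | Path | None = None
) -> Network:
    """Build a network from a reaction TSV (id, equation, pathways, ec,
    proteins) and an optional explicit link TSV (protein_id, reaction_id
    [, active]). Unknown metabolites are auto-registered; proteins named in
    either table are created without locations (localization fills them)."""
    df = _read_tsv(reaction_table, ["id", "equation"])
    network = Network()
    for i, row in df.iterrows():
        try:
            subs, prods, reversible = parse_equation(row["equation"])
        except EquationError as exc:
            raise EquationError(f"{reaction_table}, line {i + 2}: {exc}") from exc
        rxn = Reaction(
            id=row["id"],
            substrates=subs,
            products=prods,
            reversible=reversible,
            pathways=set(_split(row.get("pathways", ""))),
            ec=row.get("ec", ""),
        )
        if "locations" in df.columns and row["locations"]:
            for token in _split(row["locations"]):
                code, _, prov = token.partition(":")
                rxn.set_location(check_compartment(code), prov or "protein")
            network.localized = True
        network.add_reaction(rxn)
        for pid in _split(row.get("proteins", "")):
            network.add_protein(Protein(pid))
            if network.get_link(pid, rxn.id) is None:
                network.add_link(pid, rxn.id)
    if link_table is not None:
        ldf = _read_tsv(link_table, ["protein_id", "reaction_id"])
        for _, row in ldf.iterrows():
            network.add_protein(Protein(row["protein_id"]))
            link = network.get_link(row["protein_id"], row["reaction_id"])
            if link is None:
                link = network.add_link(row["protein_id"], row["reaction_id"])
            if "active" in ldf.columns:
                link.active = row["active"].lower() in ("1", "true", "yes")
    return network


def write_network(network: Network, outdir: str | Path) -> None:
    """Dump the full network state (reactions with provenance-tagged
    locations, proteins with sources, soft-deleted links, transports) as
    TSVs that :func:`read_network_dir` restores exactly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_rows(
        outdir / "reactions.tsv",
        ["id", "equation", "pathways", "ec", "locations"],
        (
            (
                r.id,
                format_equation(r),
                ";".join(sorted(r.pathways)),
                r.ec,
                ";".join(f"{c}:{p}" for c, p in sorted(r.locations.items())),
            )
            for r in sorted(network.reactions.values(), key=lambda r: r.id)
        ),
    )
    _write_rows(
        outdir / "metabolites.tsv",
        ["id", "name"],
        ((m.id, m.name) for m in sorted(network.metabolites.values(), key=lambda m: m.id)),
    )
    _write_rows(
        outdir / "proteins.tsv",
        ["id", "locations"],
        (
            (
                p.id,
                ";".join(
                    f"{c}:{'|'.join(sorted(srcs))}"
                    for c, srcs in sorted(p.locations.items())
                ),
            )
            for p in sorted(network.proteins.values(), key=lambda p: p.id)
        ),
    )
    _write_rows(
        outdir / "links.tsv",
        ["protein_id", "reaction_id", "active", "note"],
        (
            (l.protein_id, l.reaction_id, str(l.active).lower(), l.note)
            for l in sorted(network.links, key=lambda l: (l.protein_id, l.reaction_id))
        ),
    )
    write_transports(network.transports, outdir / "transports.tsv")


def read_network_dir(indir: str | Path) -> Network:
    """Inverse of :func:`write_network`."""
    indir = Path(indir)
    network = read_network(indir / "reactions.tsv")
    mdf = _read_tsv(indir / "metabolites.tsv", ["id", "name"])
    for _, row in mdf.iterrows():
        network.ensure_metabolite(row["id"]).name = row["name"]
    pdf = _read_tsv(indir / "proteins.tsv", ["id", "locations"])
    for _, row in pdf.iterrows():
        protein = network.add_protein(Protein(row["id"]))
        for token in _split(row["locations"]):
            code, _, srcs = token.partition(":")
            for src in _split(srcs, "|"):
                protein.add_location(code, src)
    ldf = _read_tsv(indir / "links.tsv", ["protein_id", "reaction_id", "active", "note"])
    for _, row in ldf.iterrows():
        link = network.get_link(row["protein_id"], row["reaction_id"])
        if link is None:
            link = network.add_link(row["protein_id"], row["reaction_id"])
        link.active = row["active"] == "true"
        link.note = row["note"]
    tpath = indir / "transports.tsv"
    if tpath.exists():
        network.transports = read_transport_reactions(tpath)
        for t in network.transports:
            network.ensure_metabolite(t.metabolite_id)
    return network


# ---------------------------------------------------------------------------
# Annotation tables


def read_associations(path: str | Path) -> list[tuple[str, str]]:
    """Protein-to-ontology-term pairs (GAF-like two-column TSV)."""
    df = _read_tsv(path, ["protein_id", "term_id"])
    return list(df[["protein_id", "term_id"]].itertuples(index=False, name=None))


def read_keywords(
    path: str | Path, keyword_map: Mapping[str, str] | None = None
) -> list[tuple[str, str]]:
    """Protein-to-keyword rows, resolved to compartment codes.

    Unknown keywords are logged and skipped (the default map covers the six
    organelle keywords)."""
    from .ontology import resolve_keywords

    df = _read_tsv(path, ["protein_id", "keyword"])
    pairs = list(df[["protein_id", "keyword"]].itertuples(index=False, name=None))
    return resolve_keywords(pairs, keyword_map)


def read_currency(path: str | Path) -> frozenset[str]:
    """One metabolite id per line; '#' comments allowed."""
    out = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            out.add(token)
    return frozenset(out)


def read_target_map(path: str | Path) -> dict[str, str]:
    """YAML mapping ontology term id -> compartment code."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping")
    return {str(k): check_compartment(str(v)) for k, v in data.items()}


# ---------------------------------------------------------------------------
# Evidence / curation tables


def read_type_c_verdicts(path: str | Path) -> dict[str, tuple[str, str]]:
    """Rows (reaction_id, compartment, citation): the reaction id names any
    member of the complementary group the verdict applies to."""
    df = _read_tsv(path, ["reaction_id", "compartment"])
    out = {}
    for _, row in df.iterrows():
        out[row["reaction_id"]] = (
            check_compartment(row["compartment"]),
            row.get("citation", ""),
        )
    return out


def read_gap_evidence(path: str | Path) -> dict[tuple[str, str], GapEvidence]:
    df = _read_tsv(path, ["reaction_id", "compartment"])
    out = {}
    for _, row in df.iterrows():
        key = (row["reaction_id"], check_compartment(row["compartment"]))
        out[key] = GapEvidence(
            reaction_id=key[0],
            compartment=key[1],
            new_proteins=tuple(_split(row.get("new_proteins", ""))),
            citation=row.get("citation", ""),
        )
    return out


def read_irlr_evidence(path: str | Path) -> dict[tuple[str, str], IRLREvidence]:
    df = _read_tsv(path, ["reaction_id", "compartment", "verdict"])
    out: dict[tuple[str, str], IRLREvidence] = {}
    for _, row in df.iterrows():
        key = (row["reaction_id"], check_compartment(row["compartment"]))
        verdict = row["verdict"]
        if verdict not in ("keep", "bad-link"):
            raise ValueError(f"{path}: verdict must be keep or bad-link, got {verdict!r}")
        if key in out and out[key].verdict != verdict:
            raise ValueError(
                f"{path}: conflicting verdicts for {key}: "
                f"{out[key].verdict} vs {verdict}"
            )
        out[key] = IRLREvidence(
            reaction_id=key[0],
            compartment=key[1],
            verdict=verdict,
            protein_id=row.get("protein_id", ""),
            citation=row.get("citation", ""),
        )
    return out


def read_edits(path: str | Path) -> list[CurationEdit]:
    df = _read_tsv(path, ["order", "kind", "reaction_id"])
    edits = []
    for _, row in df.iterrows():
        edits.append(
            CurationEdit(
                order=int(row["order"]),
                kind=row["kind"],
                reaction_id=row["reaction_id"],
                protein_id=row.get("protein_id", ""),
                compartments=tuple(_split(row.get("compartments", ""))),
                citation=row.get("citation", ""),
            )
        )
    return edits


def read_reference_transports(path: str | Path) -> list[ReferenceTransport]:
    df = _read_tsv(path, ["metabolite_id", "comp_from", "comp_to", "score"])
    rows = []
    for _, row in df.iterrows():
        rows.append(
            ReferenceTransport(
                metabolite_id=row["metabolite_id"],
                comp_from=check_compartment(row["comp_from"]),
                comp_to=check_compartment(row["comp_to"]),
                score=int(row["score"]),
                protein_ids=tuple(_split(row.get("proteins", ""))),
                reversible=row.get("reversible", "true").lower()
                in ("1", "true", "yes", ""),
                transporter_annotation=row.get("transporter_annotation", "").lower()
                in ("1", "true", "yes"),
            )
        )
    return rows


def read_transport_reactions(path: str | Path) -> list[TransportReaction]:
    df = _read_tsv(
        path, ["id", "metabolite_id", "comp_from", "comp_to", "reversible", "source"]
    )
    return [
        TransportReaction(
            id=row["id"],
            metabolite_id=row["metabolite_id"],
            comp_from=row["comp_from"],
            comp_to=row["comp_to"],
            reversible=row["reversible"] == "true",
            source=row["source"],
            protein_ids=tuple(_split(row.get("proteins", ""))),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Report writers


def write_transports(transports: Iterable[TransportReaction], path: str | Path) -> None:
    _write_rows(
        Path(path),
        ["id", "metabolite_id", "comp_from", "comp_to", "reversible", "source", "proteins"],
        (
            (
                t.id,
                t.metabolite_id,
                t.comp_from,
                t.comp_to,
                str(t.reversible).lower(),
                t.source,
                ";".join(t.protein_ids),
            )
            for t in sorted(transports, key=lambda t: t.id)
        ),
    )


def write_gap_report(gaps: Iterable[GapRecord], path: str | Path) -> None:
    _write_rows(
        Path(path),
        [
            "reaction_id",
            "pathway",
            "compartment",
            "component_pair",
            "locations_at_detection",
            "action",
            "citation",
        ],
        (
            (
                g.reaction_id,
                g.pathway,
                g.compartment,
                "|".join(g.component_pair),
                ";".join(sorted(g.locations_at_detection)),
                g.action,
                g.citation,
            )
            for g in gaps
        ),
    )


def write_irlr_report(irlrs: Iterable[IRLRRecord], path: str | Path) -> None:
    _write_rows(
        Path(path),
        [
            "reaction_id",
            "compartment",
            "pathways",
            "proteins",
            "other_locations",
            "other_reactions",
            "decision",
            "citation",
        ],
        (
            (
                r.reaction_id,
                r.compartment,
                ";".join(r.pathways),
                ";".join(r.proteins),
                ";".join(
                    f"{p}:{'|'.join(r.protein_other_locations.get(p, ()))}"
                    for p in r.proteins
                ),
                ";".join(
                    f"{p}:{'|'.join(r.protein_other_reactions.get(p, ()))}"
                    for p in r.proteins
                ),
                r.decision,
                r.citation,
            )
            for r in irlrs
        ),
    )


def write_dead_ends(dead_ends: Iterable[DeadEnd], path: str | Path) -> None:
    _write_rows(
        Path(path),
        ["metabolite_id", "compartment", "mode"],
        (
            (d.metabolite_id, d.compartment, d.mode)
            for d in sorted(dead_ends, key=lambda d: (d.metabolite_id, d.compartment))
        ),
    )


def write_rejections(rejections: Iterable[RejectedTransport], path: str | Path) -> None:
    _write_rows(
        Path(path),
        ["metabolite_id", "comp_from", "comp_to", "score", "reason"],
        (
            (
                r.candidate.metabolite_id,
                r.candidate.comp_from,
                r.candidate.comp_to,
                r.candidate.score,
                r.reason,
            )
            for r in rejections
        ),
    )


def write_audit_log(log: Iterable[AuditEntry], path: str | Path) -> None:
    _write_rows(
        Path(path),
        ["order", "kind", "reaction_id", "protein_id", "compartments", "accepted",
         "before", "after", "message", "citation"],
        (
            (
                e.edit.order,
                e.edit.kind,
                e.edit.reaction_id,
                e.edit.protein_id,
                ";".join(e.edit.compartments),
                str(e.accepted).lower(),
                e.before,
                e.after,
                e.message,
                e.edit.citation,
            )
            for e in log
        ),
    )


def stage_matrix(stage_counts: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Compartment x stage matrix of reaction-location counts (stages as
    given, compartments in canonical order)."""
    df = pd.DataFrame(
        {
            stage: {c: counts.get(c, 0) for c in ALL_COMPARTMENTS}
            for stage, counts in stage_counts.items()
        }
    )
    df.index.name = "location"
    return df


def pathway_location_matrix(network: Network) -> pd.DataFrame:
    """Pathway x compartment matrix of located-reaction fractions."""
    rows = {}
    for pathway in sorted(network.pathway_index):
        members = network.pathway_reactions(pathway)
        total = len(members)
        rows[pathway] = {
            c: round(
                sum(1 for r in members if c in r.locations) / total, 3
            )
            for c in ALL_COMPARTMENTS
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "pathway"
    return df


# ---------------------------------------------------------------------------
# SBML export


def write_sbml(network: Network, path: str | Path) -> None:
    """SBML Level 3 export: one species per (metabolite, compartment) with
    the usual suffix convention, each located reaction instantiated once
    per compartment, transports as distinct two-compartment reactions."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId("compartnet_export")

    used_comps: set[str] = set()
    for rxn in network.reactions.values():
        used_comps |= {c for c in rxn.locations if c != "U"}
    for t in network.transports:
        used_comps |= {t.comp_from, t.comp_to}
    for code in [c for c in ALL_COMPARTMENTS if c in used_comps]:
        comp = model.createCompartment()
        comp.setId(SBML_SUFFIX[code])
        comp.setName(code)
        comp.setConstant(True)

    species_ids: set[str] = set()

    def species(met_id: str, code: str) -> str:
        sid = _sbml_safe(f"{met_id}_{SBML_SUFFIX[code]}")
        if sid not in species_ids:
            sp = model.createSpecies()
            sp.setId(sid)
            sp.setName(met_id)
            sp.setCompartment(SBML_SUFFIX[code])
            sp.setHasOnlySubstanceUnits(False)
            sp.setBoundaryCondition(False)
            sp.setConstant(False)
            species_ids.add(sid)
        return sid

    for rxn in sorted(network.reactions.values(), key=lambda r: r.id):
        for code in sorted(c for c in rxn.locations if c != "U"):
            sr = model.createReaction()
            sr.setId(_sbml_safe(f"{rxn.id}_{SBML_SUFFIX[code]}"))
            sr.setName(rxn.id)
            sr.setReversible(rxn.reversible)
            for met, coeff in rxn.substrates:
                ref = sr.createReactant()
                ref.setSpecies(species(met, code))
                ref.setStoichiometry(coeff)
                ref.setConstant(True)
            for met, coeff in rxn.products:
                ref = sr.createProduct()
                ref.setSpecies(species(met, code))
                ref.setStoichiometry(coeff)
                ref.setConstant(True)
    for t in sorted(network.transports, key=lambda t: t.id):
        sr = model.createReaction()
        sr.setId(_sbml_safe(t.id))
        sr.setReversible(t.reversible)
        ref = sr.createReactant()
        ref.setSpecies(species(t.metabolite_id, t.comp_from))
        ref.setStoichiometry(1.0)
        ref.setConstant(True)
        ref = sr.createProduct()
        ref.setSpecies(species(t.metabolite_id, t.comp_to))
        ref.setStoichiometry(1.0)
        ref.setConstant(True)

    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):  # pragma: no cover
        raise RuntimeError(doc.getErrorLog().toString())
    libsbml.writeSBMLToFile(doc, str(path))


def _sbml_safe(raw: str) -> str:
    out = [ch if (ch.isalnum() or ch == "_") else "_" for ch in raw]
    sid = "".join(out)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "x_" + sid
    return sid
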