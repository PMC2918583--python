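"""Pipeline orchestration: the fixed stage order, snapshots and outputs.

Stage order::

    protein localization -> reaction localization -> type-c revision ->
    gap filling -> IRLR revision -> literature (curation) edits ->
    uncertain->cytosol reassignment -> reference transport import ->
    dead-end inference -> reports

After each location-revising stage a per-compartment snapshot of
reaction-location counts is retained, yielding the compartment x stage
distribution matrix. Every analysis re-derives its pathway graphs from the
current network state, so later stages see earlier revisions.

The pipeline itself is deterministic; the run seed exists for the
synthetic-data generator and is recorded in the summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import io_tables
from .curation import AuditEntry, CurationEdit, apply_edits
from .gap_irlr import (
    GapEvidence,
    GapRecord,
    IRLREvidence,
    IRLRRecord,
    SCOPE_ALL_PATHWAYS,
    decide_irlrs,
    fill_gaps,
    identify_gaps,
    identify_irlrs,
)
from .model import ALL_COMPARTMENTS, Network, validate
from .ontology import (
    Ontology,
    apply_assignments,
    localize_all,
    parse_ontology,
)
from .pathway_graph import (
    DEFAULT_CURRENCY,
    EDGE_RULE_FLOW,
    build_graph,
    to_dot,
)
from .reaction_location import (
    LinkDeletion,
    classify_all,
    find_complementary_groups,
    localize_reactions,
    resolve_type_c,
)
from .transport import (
    DeadEnd,
    ReferenceTransport,
    RejectedTransport,
    dedup_transports,
    find_dead_ends,
    import_reference,
    infer_transports,
    reassign_uncertain,
)

logger = logging.getLogger(__name__)

STAGES = (
    "original",
    "type-c-revision",
    "gap-filling",
    "irlr-revision",
    "literature-revision",
)


@dataclass
class RunOptions:
    edge_rule: str = EDGE_RULE_FLOW
    irlr_scope: str = SCOPE_ALL_PATHWAYS
    sole_participant: bool = True
    strict_curation: bool = False
    seed: int = 0


@dataclass
class PipelineResult:
    network: Network
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    classification: dict[str, int] = field(default_factory=dict)
    type_c_deletions: list[LinkDeletion] = field(default_factory=list)
    n_type_c_groups: int = 0
    gaps: list[GapRecord] = field(default_factory=list)
    gap_counts: dict[str, int] = field(default_factory=dict)
    irlrs: list[IRLRRecord] = field(default_factory=list)
    irlr_counts: dict[str, int] = field(default_factory=dict)
    audit_log: list[AuditEntry] = field(default_factory=list)
    moved_to_cytosol: int = 0
    accepted_reference: list = field(default_factory=list)
    rejected_reference: list[RejectedTransport] = field(default_factory=list)
    dead_ends: list[DeadEnd] = field(default_factory=list)
    residual_dead_ends: list[DeadEnd] = field(default_factory=list)
    n_inferred_transports: int = 0
    n_duplicate_transports: int = 0

    def summary(self) -> dict:
        """Flat, JSON-serializable run summary."""
        out: dict = {"seed": None}
        for stage, counts in self.stage_counts.items():
            for code in ALL_COMPARTMENTS:
                out[f"count[{stage}][{code}]"] = counts.get(code, 0)
        out.update(
            {
                "classification": dict(sorted(self.classification.items())),
                "type_c_groups": self.n_type_c_groups,
                "type_c_deletions": len(self.type_c_deletions),
                "gap_records": len(self.gaps),
                "gap_reactions": len({g.reaction_id for g in self.gaps}),
                "gap_counts": dict(sorted(self.gap_counts.items())),
                "irlr_records": len(self.irlrs),
                "irlr_counts": dict(sorted(self.irlr_counts.items())),
                "curation_edits_applied": sum(1 for e in self.audit_log if e.accepted),
                "moved_to_cytosol": self.moved_to_cytosol,
                "reference_accepted": len(self.accepted_reference),
                "reference_rejected": len(self.rejected_reference),
                "dead_ends": len(self.dead_ends),
                "inferred_transports": self.n_inferred_transports,
                "duplicate_transports": self.n_duplicate_transports,
                "total_transports": len(self.network.transports),
                "residual_dead_ends": len(self.residual_dead_ends),
            }
        )
        return out


def location_counts(network: Network) -> dict[str, int]:
    """Reaction-location relationships per compartment."""
    counts: dict[str, int] = {}
    for rxn in network.reactions.values():
        for code in rxn.locations:
            counts[code] = counts.get(code, 0) + 1
    return counts


def localize_network(
    network: Network,
    associations,
    keywords,
    ontology: Ontology,
    target_map: Mapping[str, str] | None = None,
) -> dict[str, int]:
    """Protein + reaction localization from annotation tables; returns the
    per-compartment protein summary counts."""
    assignments, counts = localize_all(associations, keywords, ontology, target_map)
    apply_assignments(network, assignments)
    localize_reactions(network)
    return counts


def run_stages(
    network: Network,
    currency: frozenset[str] = DEFAULT_CURRENCY,
    *,
    type_c_verdicts: Mapping[str, tuple[str, str]] | None = None,
    gap_evidence: Mapping[tuple[str, str], GapEvidence] | None = None,
    irlr_evidence: Mapping[tuple[str, str], IRLREvidence] | None = None,
    edits: list[CurationEdit] | None = None,
    reference: list[ReferenceTransport] | None = None,
    options: RunOptions | None = None,
    stop_after: str | None = None,
) -> PipelineResult:
    """Run the revision and transport stages on a localized network.

    ``stop_after`` (one of ``localize``/``type-c``/``gaps``/``irlr``/
    ``curation``/``transport``) truncates the pipeline; omitted stages
    contribute no snapshot column.
    """
    if not network.localized:
        raise ValueError("network must be localized before running the pipeline")
    options = options or RunOptions()
    result = PipelineResult(network=network)
    result.stage_counts["original"] = location_counts(network)
    result.classification = _classification_counts(network)
    if stop_after == "localize":
        return result

    # -- type-c revision ---------------------------------------------------
    groups = find_complementary_groups(network)
    result.n_type_c_groups = len(groups)
    for group in groups:
        for rid in sorted(group.reaction_ids):
            verdict = (type_c_verdicts or {}).get(rid)
            if verdict is not None:
                code, citation = verdict
                result.type_c_deletions.extend(
                    resolve_type_c(network, group, code, citation)
                )
                break
    result.stage_counts["type-c-revision"] = location_counts(network)
    if stop_after == "type-c":
        return result

    # -- gap filling -------------------------------------------------------
    result.gaps = identify_gaps(network, currency, options.edge_rule)
    result.gap_counts = fill_gaps(network, result.gaps, gap_evidence)
    result.stage_counts["gap-filling"] = location_counts(network)
    if stop_after == "gaps":
        return result

    # -- IRLR revision (graphs re-derived after filling) -------------------
    result.irlrs = identify_irlrs(
        network, currency, options.edge_rule, options.irlr_scope
    )
    result.irlr_counts = decide_irlrs(network, result.irlrs, irlr_evidence)
    result.stage_counts["irlr-revision"] = location_counts(network)
    if stop_after == "irlr":
        return result

    # -- literature-based revision ----------------------------------------
    result.audit_log = apply_edits(network, edits or [], options.strict_curation)
    result.stage_counts["literature-revision"] = location_counts(network)
    if stop_after == "curation":
        return result

    # -- transports --------------------------------------------------------
    result.moved_to_cytosol = reassign_uncertain(network)
    accepted, rejected = import_reference(network, reference or [])
    result.accepted_reference = accepted
    result.rejected_reference = rejected
    network.transports = accepted
    result.dead_ends = find_dead_ends(
        network, currency, options.sole_participant
    )
    inferred = infer_transports(network, result.dead_ends, existing=accepted)
    result.n_inferred_transports = len(inferred)
    network.transports, result.n_duplicate_transports = dedup_transports(
        accepted + inferred
    )
    result.residual_dead_ends = find_dead_ends(
        network, currency, options.sole_participant
    )
    return result


def _classification_counts(network: Network) -> dict[str, int]:
    counts: dict[str, int] = {"a": 0, "b": 0, "c": 0, "d": 0, "unknown": 0, "unlinked": 0}
    for rid, kind in classify_all(network).items():
        counts[kind if kind is not None else "unlinked"] += 1
    return counts


# ---------------------------------------------------------------------------
# File-level orchestration


@dataclass
class RunConfig:
    """Paths and options of one pipeline run; loadable from YAML."""

    reaction_table: str
    associations: str
    ontology: str
    outdir: str
    link_table: str | None = None
    keywords: str | None = None
    target_map: str | None = None
    currency: str | None = None
    type_c_verdicts: str | None = None
    gap_evidence: str | None = None
    irlr_evidence: str | None = None
    edits: str | None = None
    reference_transports: str | None = None
    edge_rule: str = EDGE_RULE_FLOW
    irlr_scope: str = SCOPE_ALL_PATHWAYS
    sole_participant: bool = True
    strict_curation: bool = False
    seed: int = 0
    stop_after: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        base = Path(path).parent
        cfg = cls(**data)
        for name in (
            "reaction_table", "associations", "ontology", "link_table",
            "keywords", "target_map", "currency", "type_c_verdicts",
            "gap_evidence", "irlr_evidence", "edits", "reference_transports",
        ):
            value = getattr(cfg, name)
            if value is not None and not Path(value).is_absolute():
                setattr(cfg, name, str(base / value))
        return cfg

    @classmethod
    def for_input_dir(cls, indir: str | Path, outdir: str | Path) -> "RunConfig":
        """Config following the conventional input-directory layout (as
        written by the simulate command); optional files are picked up when
        present."""
        indir = Path(indir)

        def opt(name: str) -> str | None:
            p = indir / name
            return str(p) if p.exists() else None

        return cls(
            reaction_table=str(indir / "reactions.tsv"),
            associations=str(indir / "associations.tsv"),
            ontology=str(indir / "ontology.obo"),
            outdir=str(outdir),
            keywords=opt("keywords.tsv"),
            target_map=opt("target_map.yaml"),
            currency=opt("currency.txt"),
            type_c_verdicts=opt("type_c_verdicts.tsv"),
            gap_evidence=opt("gap_evidence.tsv"),
            irlr_evidence=opt("irlr_evidence.tsv"),
            edits=opt("edits.tsv"),
            reference_transports=opt("reference_transports.tsv"),
        )


def load_inputs(config: RunConfig):
    """Read every input referenced by a config."""
    network = io_tables.read_network(config.reaction_table, config.link_table)
    associations = io_tables.read_associations(config.associations)
    keywords = (
        io_tables.read_keywords(config.keywords) if config.keywords else []
    )
    ontology = parse_ontology(config.ontology)
    target_map = (
        io_tables.read_target_map(config.target_map) if config.target_map else None
    )
    currency = (
        io_tables.read_currency(config.currency)
        if config.currency
        else DEFAULT_CURRENCY
    )
    verdicts = (
        io_tables.read_type_c_verdicts(config.type_c_verdicts)
        if config.type_c_verdicts
        else {}
    )
    gap_ev = (
        io_tables.read_gap_evidence(config.gap_evidence)
        if config.gap_evidence
        else {}
    )
    irlr_ev = (
        io_tables.read_irlr_evidence(config.irlr_evidence)
        if config.irlr_evidence
        else {}
    )
    edits = io_tables.read_edits(config.edits) if config.edits else []
    reference = (
        io_tables.read_reference_transports(config.reference_transports)
        if config.reference_transports
        else []
    )
    return (
        network, associations, keywords, ontology, target_map, currency,
        verdicts, gap_ev, irlr_ev, edits, reference,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Full file-to-file run: read inputs, localize, run stages, write the
    output directory. Raises on a stage failure with a stage-named error."""
    (
        network, associations, keywords, ontology, target_map, currency,
        verdicts, gap_ev, irlr_ev, edits, reference,
    ) = load_inputs(config)

    problems = validate(network)
    if problems:
        raise RuntimeError("input validation failed: " + "; ".join(problems[:5]))

    protein_counts = localize_network(
        network, associations, keywords, ontology, target_map
    )
    options = RunOptions(
        edge_rule=config.edge_rule,
        irlr_scope=config.irlr_scope,
        sole_participant=config.sole_participant,
        strict_curation=config.strict_curation,
        seed=config.seed,
    )
    result = run_stages(
        network,
        currency,
        type_c_verdicts=verdicts,
        gap_evidence=gap_ev,
        irlr_evidence=irlr_ev,
        edits=edits,
        reference=reference,
        options=options,
        stop_after=config.stop_after,
    )
    write_outputs(result, config.outdir, currency, protein_counts, seed=config.seed)
    return result


def write_outputs(
    result: PipelineResult,
    outdir: str | Path,
    currency: frozenset[str] = DEFAULT_CURRENCY,
    protein_counts: Mapping[str, int] | None = None,
    seed: int = 0,
) -> None:
    """Write the complete, deterministic output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network = result.network

    io_tables.write_network(network, outdir / "network")
    io_tables.write_gap_report(result.gaps, outdir / "gaps.tsv")
    io_tables.write_irlr_report(result.irlrs, outdir / "irlrs.tsv")
    io_tables.write_dead_ends(result.dead_ends, outdir / "dead_ends.tsv")
    io_tables.write_rejections(
        result.rejected_reference, outdir / "rejected_transports.tsv"
    )
    io_tables.write_audit_log(result.audit_log, outdir / "curation_audit.tsv")
    io_tables._write_rows(
        outdir / "type_c_deletions.tsv",
        ["protein_id", "reaction_id", "reason"],
        (
            (d.protein_id, d.reaction_id, d.reason)
            for d in result.type_c_deletions
        ),
    )
    io_tables._write_rows(
        outdir / "protein_locations.tsv",
        ["protein_id", "locations"],
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

    matrix = io_tables.stage_matrix(result.stage_counts)
    matrix.to_csv(outdir / "stage_matrix.tsv", sep="\t")
    io_tables.pathway_location_matrix(network).to_csv(
        outdir / "pathway_locations.tsv", sep="\t"
    )
    io_tables.write_sbml(network, outdir / "model.sbml.xml")

    graphs_dir = outdir / "graphs"
    graphs_dir.mkdir(exist_ok=True)
    for pathway in network.analysis_pathways():
        for code in ALL_COMPARTMENTS:
            if code == "U":
                continue
            graph = build_graph(network, pathway, code, currency)
            if graph.nodes:
                safe = pathway.replace("/", "_")
                (graphs_dir / f"{safe}__{code}.dot").write_text(
                    to_dot(graph), encoding="utf-8"
                )

    summary = result.summary()
    summary["seed"] = seed
    if protein_counts is not None:
        summary["protein_counts"] = {
            c: protein_counts.get(c, 0) for c in ALL_COMPARTMENTS
        }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
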