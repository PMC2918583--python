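"""Gap identification/filling and IRLR identification/decision rules."""

import pytest

from compartnet.gap_irlr import (
    GapEvidence,
    IRLREvidence,
    decide_irlrs,
    fill_gaps,
    identify_gaps,
    identify_irlrs,
)
from compartnet.model import Network, Protein, Reaction
from compartnet.pathway_graph import build_graph, components
from compartnet.synthetic import (
    GeneratorConfig,
    generate,
    oracle_gap_records,
    _apply_true_locations,
)


def test_single_gap_fixture_bridges_two_components(single_gap):
    gaps = identify_gaps(single_gap)
    assert len(gaps) == 1
    gap = gaps[0]
    assert (gap.reaction_id, gap.compartment) == ("R6", "M")
    assert gap.component_pair == ("R1", "R7")
    assert gap.locations_at_detection == frozenset({"U"})


def test_single_component_pathway_has_no_gaps():
    net = Network()
    for i, (s, p) in enumerate([("A", "B"), ("B", "C")], 1):
        r = Reaction(f"R{i}", [(s, 1.0)], [(p, 1.0)], False, {"pw"})
        r.set_location("M", "protein")
        net.add_reaction(r)
    net.localized = True
    assert identify_gaps(net) == []


def test_gaps_never_report_already_held_locations(default_data):
    net = default_data.network.copy()
    data = default_data
    probe = type(data)(
        network=net, associations=data.associations, keywords=data.keywords,
        ontology=data.ontology, target_map=data.target_map,
        currency=data.currency, ground_truth=data.ground_truth,
    )
    _apply_true_locations(probe)
    for gap in identify_gaps(net, data.currency):
        assert gap.compartment not in net.reactions[gap.reaction_id].locations


def test_identify_gaps_matches_exhaustive_enumeration_on_planted_networks():
    """Per component-pair agreement with brute-force enumeration on
    generated planted-gap networks of varying shape."""
    for seed in range(25):
        config = GeneratorConfig(
            seed=seed,
            n_pathways=6 + seed % 4,
            n_gaps=1 + seed % 3,
            n_irlrs=seed % 2,
            n_dead_ends=seed % 2,
        )
        data = generate(config)
        _apply_true_locations(data)
        net = data.network
        got = {
            (g.reaction_id, g.pathway, g.compartment, g.component_pair)
            for g in identify_gaps(net, data.currency)
        }
        assert got == oracle_gap_records(net, data.currency)


def test_auto_fill_moves_uncertain_reaction(single_gap):
    gaps = identify_gaps(single_gap)
    counts = fill_gaps(single_gap, gaps)
    assert counts == {"auto-filled": 1, "evidence-filled": 0, "unfilled": 0, "fills": 1}
    rxn = single_gap.reactions["R6"]
    assert rxn.locations == {"M": "gap-filled"}
    graph = build_graph(single_gap, "example-pathway", "M")
    assert len(components(graph)) == 1
    assert identify_irlrs(single_gap) == []


def test_evidence_fill_adds_location_and_links():
    """A gap on a located reaction fills only with evidence, which may
    introduce the newly implicated enzymes."""
    net = Network()
    for rid, s, p, comp in [
        ("R1", "A", "B", "X"),
        ("R2", "B", "C", "M"),  # the gap reaction: located, but not in X
        ("R3", "C", "D", "X"),
    ]:
        r = Reaction(rid, [(s, 1.0)], [(p, 1.0)], False, {"pw"})
        r.set_location(comp, "protein")
        net.add_reaction(r)
    net.add_protein(Protein("ACOX1"))
    net.add_protein(Protein("ACOX3"))
    net.localized = True
    gaps = identify_gaps(net)
    assert [(g.reaction_id, g.compartment) for g in gaps] == [("R2", "X")]

    # without evidence: unchanged
    unfilled = fill_gaps(net, [g for g in gaps])
    assert unfilled["unfilled"] == 1
    assert "X" not in net.reactions["R2"].locations

    evidence = {
        ("R2", "X"): GapEvidence("R2", "X", ("ACOX1", "ACOX3"), "peroxisomal activity")
    }
    gaps = identify_gaps(net)
    counts = fill_gaps(net, gaps, evidence)
    assert counts["evidence-filled"] == 1 and counts["fills"] == 1
    assert net.reactions["R2"].locations["X"] == "gap-filled"
    assert {l.protein_id for l in net.links_for_reaction("R2")} == {"ACOX1", "ACOX3"}


def test_fill_gaps_rejects_unknown_evidence_entities(single_gap):
    gaps = identify_gaps(single_gap)
    with pytest.raises(KeyError):
        fill_gaps(single_gap, gaps, {("R6", "M"): GapEvidence("R6", "M", ("NOPE",))})


def test_irlr_detection_is_location_specific():
    """A reaction can be isolated in one compartment yet connected in
    another; only the isolated relationship is flagged."""
    net = Network()
    specs = [
        ("R1", "A", "B", ["M", "N"]),
        ("R2", "B", "C", ["M"]),
    ]
    for rid, s, p, comps in specs:
        r = Reaction(rid, [(s, 1.0)], [(p, 1.0)], False, {"pw"})
        for c in comps:
            r.set_location(c, "protein")
        net.add_reaction(r)
    net.localized = True
    records = identify_irlrs(net)
    assert [(r.reaction_id, r.compartment) for r in records] == [("R1", "N")]


def test_single_reaction_pathway_is_irlr():
    net = Network()
    r = Reaction("R1", [("A", 1.0)], [("B", 1.0)], False, {"lone"})
    r.set_location("L", "protein")
    net.add_reaction(r)
    net.localized = True
    records = identify_irlrs(net)
    assert [(r.reaction_id, r.compartment) for r in records] == [("R1", "L")]


def test_all_pathways_scope_requires_isolation_everywhere():
    """Connected in a second pathway context: not an IRLR by default, but
    flagged by the per-pathway variant."""
    net = Network()
    r1 = Reaction("R1", [("A", 1.0)], [("B", 1.0)], False, {"pw1", "pw2"})
    r2 = Reaction("R2", [("B", 1.0)], [("C", 1.0)], False, {"pw2"})
    for r in (r1, r2):
        r.set_location("M", "protein")
        net.add_reaction(r)
    net.localized = True
    assert identify_irlrs(net, scope="all-pathways") == []
    per = identify_irlrs(net, scope="per-pathway")
    assert [(r.reaction_id, r.compartment, r.pathways) for r in per] == [
        ("R1", "M", ("pw1",))
    ]


def test_irlr_singleton_scan_matches_planted_truth():
    for seed in (3, 4):
        data = generate(GeneratorConfig(seed=seed, n_gaps=0, n_irlrs=4, n_dead_ends=0))
        _apply_true_locations(data)
        records = identify_irlrs(data.network, data.currency)
        assert {(r.reaction_id, r.compartment) for r in records} == set(
            data.ground_truth.irlrs
        )


def test_decide_rules_on_worked_examples(worked, worked_evidence):
    _verdicts, irlr_ev = worked_evidence
    records = identify_irlrs(worked)
    decide_irlrs(worked, records, irlr_ev)
    decisions = {(r.reaction_id, r.compartment): r.decision for r in records}
    # unique single-purpose peroxisomal protein: kept by evidence
    assert decisions[("R02204", "X")] == "keep-evidence"
    assert "X" in worked.reactions["R02204"].locations
    # protein also present elsewhere, no evidence: compartment removed
    assert decisions[("R03631", "ER")] == "remove"
    assert set(worked.reactions["R03631"].locations) == {"X"}
    # busy multi-location protein: cytosol annotation deleted
    assert decisions[("R05989", "C")] == "remove"
    assert "C" not in worked.reactions["R05989"].locations
    # wrong protein-reaction association: link deactivated, not location-edited
    assert decisions[("R04586", "C")] == "remove-bad-link"
    link = worked.get_link("MGEA5", "R04586")
    assert link is not None and not link.active
    assert set(worked.reactions["R04586"].locations) == {"U"}


def test_unique_protein_rule_keeps_without_evidence():
    net = Network()
    r1 = Reaction("R1", [("A", 1.0)], [("B", 1.0)], False, {"pw"})
    r1.set_location("X", "protein")
    net.add_reaction(r1)
    p = net.add_protein(Protein("PX"))
    p.add_location("X", "GO")
    net.add_link("PX", "R1")
    net.localized = True
    records = identify_irlrs(net)
    counts = decide_irlrs(net, records)
    assert counts["keep-unique-protein"] == 1
    assert "X" in net.reactions["R1"].locations


def test_removal_never_leaves_empty_locations():
    net = Network()
    r1 = Reaction("R1", [("A", 1.0)], [("B", 1.0)], False, {"pw"})
    r1.set_location("N", "protein")
    net.add_reaction(r1)
    p = net.add_protein(Protein("PN"))
    p.add_location("N", "GO")
    p.add_location("C", "GO")
    net.add_link("PN", "R1")
    net.localized = True
    records = identify_irlrs(net)
    decide_irlrs(net, records)
    assert net.reactions["R1"].locations == {"U": "default-uncertain"}


def test_records_are_deterministically_sorted(default_data):
    data = default_data
    probe_net = data.network.copy()
    probe = type(data)(
        network=probe_net, associations=data.associations, keywords=data.keywords,
        ontology=data.ontology, target_map=data.target_map,
        currency=data.currency, ground_truth=data.ground_truth,
    )
    _apply_true_locations(probe)
    a = identify_gaps(probe_net, data.currency)
    b = identify_gaps(probe_net, data.currency)
    assert [(g.reaction_id, g.pathway, g.compartment) for g in a] == [
        (g.reaction_id, g.pathway, g.compartment) for g in b
    ]
    keys = [(g.pathway, g.compartment, g.reaction_id, g.component_pair) for g in a]
    assert keys == sorted(keys)
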