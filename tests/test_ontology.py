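"""Ontology parsing, backtracking and protein localization."""

import random
from io import StringIO

import pytest
from hypothesis import given, settings, strategies as st

from compartnet.ontology import (
    Ontology,
    OntologyTerm,
    backtrack,
    localize_all,
    localize_protein,
    parse_ontology,
    resolve_keywords,
)
from compartnet.synthetic import build_mini_ontology, mini_ontology_obo


@pytest.fixture(scope="module")
def mini():
    return build_mini_ontology()


def test_parse_mini_obo_structure(mini):
    ontology, _ = mini
    # root + 8*(anchor + 2 leaves) + PM + PM leaf + OFF + OBS + OBS child
    assert len(ontology) == 1 + 24 + 5
    assert ontology.terms["CN:L2_M"].parents == {("CN:T_M", "part_of")}
    assert ontology.terms["CN:L_M"].parents == {("CN:T_M", "is_a")}
    assert ontology.terms["CN:OBS"].obsolete
    assert ontology.check_edges() == []


def test_obsolete_terms_break_ancestry(mini):
    ontology, target_map = mini
    # the child of the withdrawn term cannot reach the root through it
    assert backtrack("CN:L_OBS", ontology, target_map) == {"U"}
    assert "CN:OBS" not in ontology.ancestors("CN:L_OBS")


@pytest.mark.parametrize(
    "term,expected",
    [
        ("CN:L_M", {"M"}),       # organelle sub-structure resolves upward
        ("CN:L2_M", {"M"}),      # part_of ancestry counts too
        ("CN:L_PM", {"C"}),      # plasma membrane remaps to cytosol
        ("CN:PM", {"C"}),
        ("CN:T_N", {"N"}),       # a target term resolves to itself
        ("CN:OFF", {"U"}),       # off-branch leaf: only above-target ancestors
        ("CN:ROOT", {"U"}),
    ],
)
def test_backtrack_resolution(mini, term, expected):
    ontology, target_map = mini
    assert backtrack(term, ontology, target_map) == expected


def test_backtrack_unknown_term_errors(mini):
    ontology, target_map = mini
    with pytest.raises(KeyError, match="CN:NOPE"):
        backtrack("CN:NOPE", ontology, target_map)


def test_localize_protein_merges_sources(mini):
    ontology, target_map = mini
    # conflicting sources: assign to all locations
    a = localize_protein("p1", {"CN:L_C"}, {"M"}, ontology, target_map)
    assert a.compartments == {"C", "M"}
    assert a.sources == {"C": {"GO"}, "M": {"keyword"}}
    # keyword only
    a = localize_protein("p2", set(), {"M"}, ontology, target_map)
    assert a.compartments == {"M"}
    # nothing resolvable
    a = localize_protein("p3", set(), set(), ontology, target_map)
    assert a.compartments == {"U"}
    # a real hit suppresses U coming from an uninformative term
    a = localize_protein("p4", {"CN:OFF", "CN:L_X"}, set(), ontology, target_map)
    assert a.compartments == {"X"}


def test_localize_all_counts_multi_location_proteins_once_per_compartment(mini):
    ontology, target_map = mini
    associations = [
        ("pA", "CN:L_M"),
        ("pB", "CN:L_M"),
        ("pB", "CN:L_C"),
        ("pC", "CN:OFF"),
        ("pD", "CN:L_N"),
        ("pD", "CN:L_N"),  # duplicate row merged
    ]
    keywords = [("pE", "M"), ("pC", "L")]
    assignments, counts = localize_all(associations, keywords, ontology, target_map)
    assert set(assignments) == {"pA", "pB", "pC", "pD", "pE"}
    assert counts == {"M": 3, "C": 1, "L": 1, "N": 1}
    assert assignments["pC"].compartments == {"L"}


def test_resolve_keywords_skips_unknown():
    pairs = [("p1", "Mitochondrion"), ("p1", "flagellum"), ("p2", "lysosome")]
    assert resolve_keywords(pairs) == [("p1", "M"), ("p2", "L")]


def test_parse_error_on_malformed_stream():
    from compartnet.ontology import OntologyParseError

    with pytest.raises(OntologyParseError):
        parse_ontology(StringIO("this is not an obo file\n[Term\nid broken"))


# ---------------------------------------------------------------------------
# Properties


@settings(max_examples=50, derandomize=True)
@given(st.sets(st.sampled_from(["CN:L_M", "CN:L_C", "CN:OFF", "CN:L2_X"]), max_size=4),
       st.sampled_from(["CN:L_N", "CN:L_PM"]))
def test_backtrack_monotone_in_annotations(terms, extra):
    """Adding an annotation never removes a resolved compartment."""
    ontology, target_map = build_mini_ontology()
    base = localize_protein("p", terms, set(), ontology, target_map)
    more = localize_protein("p", terms | {extra}, set(), ontology, target_map)
    assert base.compartments - {"U"} <= more.compartments


def random_dag(rng: random.Random, n_terms: int) -> Ontology:
    """Random DAG: each term points to lower-indexed parents only."""
    terms = {}
    for i in range(n_terms):
        parents = set()
        for j in range(i):
            if rng.random() < 0.15:
                parents.add((f"T{j}", rng.choice(["is_a", "part_of"])))
        terms[f"T{i}"] = OntologyTerm(f"T{i}", parents=parents)
    return Ontology(terms)


def closure_oracle(ontology: Ontology, term: str) -> set[str]:
    """Exhaustive ancestor enumeration by fixed-point iteration over the
    full parent relation (independent of Ontology.ancestors)."""
    reach = {term}
    changed = True
    while changed:
        changed = False
        for t in list(reach):
            for parent, _rel in ontology.terms[t].parents:
                if parent not in reach:
                    reach.add(parent)
                    changed = True
    return reach


def test_backtrack_matches_exhaustive_closure_on_random_dags():
    rng = random.Random(42)
    for _ in range(200):
        n = rng.randint(5, 50)
        ontology = random_dag(rng, n)
        target_ids = rng.sample(sorted(ontology.terms), k=min(4, n))
        codes = ["M", "C", "N", "X"]
        target_map = {t: codes[i % 4] for i, t in enumerate(target_ids)}
        probe = rng.choice(sorted(ontology.terms))
        expected = {
            target_map[t] for t in closure_oracle(ontology, probe) if t in target_map
        } or {"U"}
        assert backtrack(probe, ontology, target_map) == expected


def test_backtrack_invariant_under_edge_and_term_order():
    rng = random.Random(7)
    ontology = random_dag(rng, 30)
    target_map = {"T0": "M", "T3": "C"}
    expected = {t: backtrack(t, ontology, target_map) for t in ontology.terms}
    shuffled = Ontology(
        {k: ontology.terms[k] for k in sorted(ontology.terms, reverse=True)}
    )
    for t in shuffled.terms:
        assert backtrack(t, shuffled, target_map) == expected[t]
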