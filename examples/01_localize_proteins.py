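"""Protein localization by ontology backtracking.

Builds the bundled mini cellular-component ontology, annotates a few
proteins to sub-organelle terms, and resolves each to the eight top-level
compartments (plus the uncertain placeholder U).
"""

from compartnet.ontology import localize_protein
from compartnet.synthetic import build_mini_ontology

ontology, target_map = build_mini_ontology()

cases = [
    ("ENZ1", {"CN:L_M"}, set()),          # a mitochondrial sub-structure
    ("ENZ2", {"CN:L_PM"}, set()),         # plasma membrane -> cytosol
    ("ENZ3", {"CN:OFF"}, set()),          # uninformative branch -> uncertain
    ("ENZ4", {"CN:L_C"}, {"M"}),          # GO says cytosol, keyword says M
    ("ENZ5", set(), set()),               # no annotation at all
]

for pid, terms, keywords in cases:
    assignment = localize_protein(pid, terms, keywords, ontology, target_map)
    print(f"{pid}: terms={sorted(terms) or '-'} keywords={sorted(keywords) or '-'}"
          f" -> compartments {sorted(assignment.compartments)}")

print()
print("Reading: ENZ2 lands in C because plasma-membrane proteins catalyse")
print("cytosolic chemistry; ENZ4 keeps both sources (assign-to-all policy);")
print("ENZ3/ENZ5 fall back to U, the uncertain placeholder.")
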