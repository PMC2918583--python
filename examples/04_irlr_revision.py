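"""Isolated reaction-location relationship (IRLR) revision.

Identifies one-node components in the compartment-specific pathway graphs
of the worked-example network and applies the decision rules: keep on
literature evidence, keep when the enzyme is unique to that compartment
and reaction, delete a bad protein-reaction link when evidence says so,
remove the location otherwise.
"""

from compartnet.gap_irlr import decide_irlrs, identify_irlrs
from compartnet.synthetic import worked_example_evidence, worked_example_fixtures

net = worked_example_fixtures()
_verdicts, irlr_evidence = worked_example_evidence()

records = identify_irlrs(net)
print(f"{len(records)} isolated reaction-location relationships found")
decide_irlrs(net, records, irlr_evidence)
for r in records:
    print(f"  ({r.reaction_id}, {r.compartment}) -> {r.decision}")

print()
print("Reading: R03631 loses its ER annotation (its enzyme is busy in the")
print("peroxisome), R05989 loses cytosol (its enzyme works elsewhere),")
print("R02204 keeps the peroxisome on direct literature evidence, and the")
print("R04586 record traces back to a wrong protein-reaction link.")
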