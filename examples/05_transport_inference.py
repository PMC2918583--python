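"""Dead-end analysis and cytosol-bridged transport inference.

A metabolite only produced in one compartment (or only consumed, or
confined to a single reaction) is a dead end there. When the same
metabolite also occurs elsewhere, reversible transport reactions through
the cytosol reconnect it.
"""

from compartnet.model import Network, Reaction
from compartnet.transport import find_dead_ends, infer_transports

net = Network()
for rid, sub, prod, comp in [
    ("R1", "precursor", "intermediate", "M"),   # produced in mitochondria
    ("R2", "intermediate", "product", "X"),     # consumed in peroxisomes
    ("R3", "other", "precursor", "M"),
]:
    rxn = Reaction(rid, [(sub, 1.0)], [(prod, 1.0)], False, {"demo"})
    rxn.set_location(comp, "protein")
    net.add_reaction(rxn)
net.localized = True

dead = find_dead_ends(net, currency=frozenset())
for d in dead:
    print(f"dead end: {d.metabolite_id} in {d.compartment} ({d.mode})")

new = infer_transports(net, dead)
net.transports = new
for t in new:
    print(f"inferred transport: {t.metabolite_id} {t.comp_from}<->{t.comp_to}")

residual = [
    d for d in find_dead_ends(net, currency=frozenset())
    if len(net.metabolite_compartments(d.metabolite_id)) >= 2
]
print("bridgeable dead ends after inference:", len(residual))
print("Reading: 'intermediate' is stranded between M and X; two reversible")
print("transports via the cytosol hub reconnect every compartment holding it.")
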