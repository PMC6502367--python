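#!/usr/bin/env python
"""Enumerate the attractors of the effective four-enzyme switching circuit.

Malic enzyme and malate dehydrogenase support each other and antagonize
aspartate transaminase and transketolase; asynchronous threshold updates
from every initial state terminate in one of two antagonistic
configurations.
"""
import json
from pathlib import Path

from metstab.landscape import BooleanCircuit, boolean_attractors

out = Path("results")
out.mkdir(exist_ok=True)

circuit = BooleanCircuit()
attractors = boolean_attractors(circuit)
doc = {
    "nodes": list(circuit.nodes),
    "interactions": circuit.interactions.tolist(),
    "attractors": [[list(s) for s in a] for a in attractors],
}
(out / "circuit.json").write_text(json.dumps(doc, indent=1) + "\n")

print(f"{len(attractors)} attractors over 2^{len(circuit.nodes)} states "
      f"-> {out/'circuit.json'}")
for a in attractors:
    kind = "fixed point" if len(a) == 1 else f"{len(a)}-cycle"
    states = ", ".join(
        "(" + " ".join(f"{n}{'+' if v > 0 else '-'}"
                        for n, v in zip(circuit.nodes, s)) + ")"
        for s in a
    )
    print(f"  {kind}: {states}")
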