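#!/usr/bin/env python
"""Probe which metabolite input/output fluxes can flip the state class.

Every internal pool is perturbed by +-0.1 flux units (supply-side probes
only where a transporter exists) on the reference condition; a pool is a
switch metabolite when the re-regulated state lands in the opposite flux
class.
"""
from pathlib import Path

import metstab as ms

out = Path("results")
model = ms.build_core_model()
ensemble = ms.default_condition_ensemble(model)
landscape = ms.scan_conditions(model, ensemble)

switches, detail = ms.probe_switch_metabolites(
    model, ensemble, landscape=landscape
)
detail.to_csv(out / "switch_metabolite_probes.tsv", sep="\t", index=False)

print(f"probed {detail.metabolite.nunique()} internal metabolites "
      f"-> {out/'switch_metabolite_probes.tsv'}")
print("class-flipping metabolites:", sorted(switches))
flips = detail[detail.flip]
if len(flips):
    print(flips.to_string(index=False))
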