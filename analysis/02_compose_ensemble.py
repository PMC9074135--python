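#!/usr/bin/env python
"""Compose the synthetic study ensemble and record its ground truth.

Generates the 500-frame Aβ16 ensemble (40% α-helical / 60% coil frames,
0.12 Å coordinate jitter) with the Glu3–Arg5 salt bridge, the His14
Nδ–H → Glu11 O hydrogen bond, and Tyr10/phenanthroline stacking injected
at 76% / 34% / 35% occupancy.  The trajectory goes to scratch/ (it is
regenerated on demand); the composition summary goes to results/.
"""

import json
from collections import Counter

from _study import RESULTS, get_ensemble, study_spec

traj, truth = get_ensemble()
spec = study_spec()

classes = Counter(truth["classes"])
summary = {
    "n_frames": traj.n_frames,
    "n_atoms": traj.topology.n_atoms,
    "sequence": spec.sequence,
    "noise_sigma": spec.noise_sigma,
    "seed": spec.seed,
    "class_counts": dict(classes),
    "injected_occupancy": {
        key: sum(flags) / len(flags)
        for key, flags in truth["injected"].items()
    },
}
(RESULTS / "study_ensemble.json").write_text(json.dumps(summary, indent=1))
print(json.dumps(summary, indent=1))
print("\nGround-truth occupancies are exact by construction; downstream "
      "scripts must recover them from geometry alone.")
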