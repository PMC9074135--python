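"""Shared study conditions for the analysis scripts.

The synthetic study emulates the room-temperature ensemble of the
Pt(phenanthroline)–Aβ16 adduct: a 500-frame Aβ16 ensemble mixing α-helical
and coil conformers (40/60), with the three hallmark interactions injected
at their observed room-temperature occupancies — the Glu3–Arg5 salt bridge
(76% of frames), the His14 Nδ–H → Glu11 backbone-O hydrogen bond (34%), and
face-to-face Tyr10/phenanthroline π-stacking at (3.55 Å, 0.18°) in 35% of
frames.  Everything is deterministic given STUDY_SEED.
"""

import json
from pathlib import Path

from idpkit.structure_io import abeta_sequences, read_pdb_models, write_pdb_models
from idpkit.synthetic import EnsembleSpec, Injection, compose_ensemble

STUDY_SEED = 2019
N_FRAMES = 500
NOISE_SIGMA = 0.12          # Å: small thermal jitter on top of the templates

SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_spec() -> EnsembleSpec:
    return EnsembleSpec(
        sequence=abeta_sequences()["abeta16"],
        n_frames=N_FRAMES,
        class_fractions={"alpha": 0.4, "coil": 0.6},
        noise_sigma=NOISE_SIGMA,
        seed=STUDY_SEED,
        injections=[
            Injection("salt_bridge", 3, 5, distance=3.0, occupancy=0.76),
            Injection("hbond", 14, 11, distance=2.9, occupancy=0.34,
                      donor_atom="ND1", acceptor_atom="O"),
            Injection("stacking", 10, distance=3.55, angle=0.18,
                      occupancy=0.35),
        ],
    )


def get_ensemble():
    """Compose (or reload from scratch/) the study ensemble + ground truth."""
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    pdb = SCRATCH / "study_ensemble.pdb"
    truth_file = SCRATCH / "study_truth.json"
    if pdb.exists() and truth_file.exists():
        traj = read_pdb_models(pdb)
        truth = json.loads(truth_file.read_text())
        return traj, truth
    traj, gt = compose_ensemble(study_spec())
    truth = {
        "classes": gt.classes,
        "injected": {k: v.astype(int).tolist() for k, v in gt.injected.items()},
    }
    write_pdb_models(traj, pdb)
    truth_file.write_text(json.dumps(truth))
    return traj, truth
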