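# idpkit

Conformational-ensemble analysis for intrinsically disordered peptides,
built around the amyloid-β (Aβ) fragments Aβ16 (`DAEFRHDSGYEVHHQK`) and
Aβ42 and their adducts with a planar Pt(II)–phenanthroline complex
coordinated at His6/His14.

Disordered peptides do not fold to a single structure; what a simulation
delivers is an *ensemble* of conformers, and the science lives in ensemble
statistics: how compact the chain is, which secondary structures it visits,
which salt bridges, hydrogen bonds and aromatic stacking contacts persist,
and how the conformers cluster.  `idpkit` computes all of these from plain
multi-model PDB trajectories, and ships a synthetic-conformer generator so
that every stage can be validated against inputs with known ground truth —
no simulation data required.

## What it computes

| quantity | definition |
|---|---|
| RMSD / RMSF | least-squares (Kabsch) superposition; RMSF_i = √⟨\|x_i − ⟨x_i⟩\|²⟩ |
| R_g and shape | gyration tensor S = Σ w_i Δx Δxᵀ/Σ w_i; λ₁ ≥ λ₂ ≥ λ₃, R_g² = tr S; anisotropy b = (λ₂+λ₃)/2λ₁ (0 = linear chain, 1 = fully symmetric) |
| secondary structure | from-scratch Kabsch–Sander (DSSP) 8-state assignment from backbone H-bond energies E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond at E < −0.5 |
| hydrogen bonds | heavy-atom distance ≤ 3.0 Å and D–H···A ≥ 135° (H reconstructed for sp2 donors); classified i+3→i / i+4→i / i+5→i / other / side-chain |
| salt bridges | any O–N < 3.2 Å between acidic oxygens and basic nitrogens; occupancy = fraction of frames |
| π-stacking | ring-centroid distance and interplanar angle from least-squares plane fits |
| contact maps | mean Cα–Cα distance matrices |
| Ramachandran | φ/ψ histograms with named-basin fractions (αR, PPII, β, γ′, αL) |
| clustering | DBSCAN (ε = 0.8 Å backbone RMSD, MinPoints = 5) with populations and medoids |
| replica exchange | geometric temperature ladders, Metropolis swap criterion, exchange-acceptance statistics |

The synthetic module builds all-heavy-atom peptides at prescribed (φ, ψ)
from standard internal coordinates, an idealized planar phenanthroline
(optionally with its chelated Pt), posed π-stacks at exact geometry,
two-strand β-sheets of either sense, labelled ensembles mixing conformer
classes at exact fractions with interactions injected at exact occupancies,
and replica-exchange logs with exact acceptance fractions.

## Worked example

```python
from idpkit import (abeta_sequences, build_peptide, build_phenanthroline,
                    assign_dssp, ss_summary)
from idpkit.geometry import gyration_of
from idpkit.structure_io import Trajectory

ab16 = abeta_sequences()["abeta16"]

top, frame = build_phenanthroline(include_platinum=True)
print(round(gyration_of(frame, top).rg, 3))        # 2.281

top, frame = build_peptide(ab16, "extended")       # φ = ψ = 180°
print(round(gyration_of(frame, top).rg, 3))        # 17.289

top, frame = build_peptide(ab16, "alpha")          # φ, ψ = −60°, −40°
print(round(gyration_of(frame, top).rg, 3))        # 8.5

labels = assign_dssp(Trajectory(top, [frame]))
print("".join(labels.labels[0]))                   # CHHHHHHHHHHHHHHC
```

The three R_g values are the calibration anchors of the package: the
Pt-bearing ligand fragment measures ≈2.3 Å, and the fully extended and
α-helical Aβ16 chains bracket the conformational range at ≈17 Å and
≈8.5 Å.  The DSSP string shows every interior residue of the ideal helix
assigned `H`.

The scripts under `analysis/` run the full study on a synthetic
500-frame Aβ16 ensemble (40 % α-helical / 60 % coil frames; Glu3–Arg5 salt
bridge at 76 % occupancy, His14 Nδ–H→Glu11 O hydrogen bond at 34 %,
Tyr10–phenanthroline stacking at 35 %) and verify that every analysis
stage recovers the generator's ground truth; run them in order
(`python analysis/01_reference_structures.py`, …).  Tables land in
`results/`, bulky intermediates in `scratch/`.

A `idpkit` command-line tool wraps the library
(`idpkit analyze rmsd|rg|ss|hbonds|saltbridges|contacts|stacking|cluster|rama`,
`idpkit synth make-ensemble`, `idpkit remd ladder|xfreq`,
`idpkit report --config config.yaml`).

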