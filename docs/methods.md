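# Methods

## Scope and data model

Everything operates on a `Trajectory`: a `Topology` (atoms, residues,
1-based residue numbering in the Asp1…Ala42 convention, HETATM fragments
flagged as ligand) plus per-frame Cartesian coordinates in Å.  Input/output
is multi-model PDB only; the parser is fixed-column (coordinates from
columns 31–54 at 3-decimal precision), tolerates a missing element column
(element inferred from the atom name), does not require sequential MODEL
numbers, and maps unknown HETATM names by element.  All analyses run on
heavy-atom-only inputs; hydrogens are reconstructed where a method needs
them.  Binary trajectory formats, mmCIF, altlocs and insertion codes are
out of scope.

## Peptide and ligand builders

Backbone N/CA/C/O atoms are placed by natural-extension (NeRF) from
internal coordinates: N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O
1.231 Å; tetrahedral N–CA–C (109.47°) and trigonal peptide-unit angles
(C–N–CA 121.7°, CA–C–N 116.2°); ω fixed at 180° (no cis-proline — the Aβ
sequences contain no proline).  The tetrahedral Cα angle was chosen so an
α-helix built at the Ramachandran basin centre (−60°, −40°) has i+4→i
O···N separations at the edge of hydrogen-bonding range (≈3.2 Å); stiffer
crystallographic values (≈111°) push them beyond 3.4 Å.  Requested φ/ψ are
reproduced exactly (measured values agree to 1e-6°).

Side chains are one fixed rotamer per residue type, taken from the
Chemical Component Dictionary ideal coordinates bundled with biotite and
attached by superposing the template's N/CA/C onto the built backbone.
This guarantees L-chirality (the N→C→CA→CB improper is ≈−120° for every
residue) and full determinism, at the cost of no rotamer diversity.

Named backbone templates: α (−60, −40), 3,10 (−49, −26), β (−150, 160),
PPII (−75, 150), extended (180, 180).  The classic α-helix (−57.8, −47)
is used in tests wherever detected H-bond geometry (rather than basin
membership) matters.  "Coil" frames draw per-residue φ/ψ from a weighted
set of basins (β, PPII, bridge, extended-polar, αL) jittered ±25°.

1,10-Phenanthroline is laid out on an exact hexagonal lattice (all
aromatic bonds 1.40 Å, three fused six-membered rings, exactly planar);
the chelating nitrogens occupy the facing bay positions of the outer
rings.  With `include_platinum=True`, Pt is placed in-plane equidistant
(2.06 Å) from both nitrogens.  The mass-weighted radius of gyration of
that Pt-bearing fragment is ≈2.28 Å — the ≈2.3 Å "ligand size" figure
that trajectory tools report for the complex; the bare ligand alone
measures ≈2.49 Å, so the heavy Pt atom (and where the mass-weighted
centre sits) is part of the definition, not a detail.

Two-strand β-sheets are built from idealized strands ((−139, 135)
antiparallel, (−119, 113) parallel), the second strand rigidly placed by a
deterministic grid search that maximizes the count of inter-strand
Kabsch–Sander hydrogen bonds.  Each strand is its own chain; chain breaks
terminate φ/ψ continuity and amide-H reconstruction.

## Composed ensembles and injections

`compose_ensemble` turns an `EnsembleSpec` (sequence, frame count, class
fractions, noise, seed, injections) into a labelled trajectory.  Class
counts are exact (largest-remainder rounding, seeded order); i.i.d.
Gaussian noise is added per coordinate; every injection is realized in
exactly `round(occupancy × n_frames)` frames and suppressed elsewhere, so
ground-truth occupancies are exact by construction even under noise:

- **salt bridge** — the acidic residue's side chain is rigidly translated
  so its closest carboxylate O sits at the requested distance from the
  basic nitrogen (non-injected frames are pushed beyond 2× the detection
  cutoff when necessary);
- **hydrogen bond** — the donor side chain is translated so the
  donor→acceptor axis runs along the donor's reconstructed H direction at
  the requested distance (iterated to self-consistency, since large
  translations can strain the local geometry);
- **stacking** — the phenanthroline is posed over the target ring at the
  requested centroid distance and interplanar angle, and parked 25 Å away
  in non-injected frames; noise on injected frames is undone for the rigid
  ligand so the posed geometry survives.

Injected frames are geometrically valid for the detectors but not
physically relaxed: side-chain translations can create strained or
clashing local geometry.  The generator emulates *composition* (class
fractions, contact occupancies, posed geometry), not physics: there is no
forcefield, no solvent, no Boltzmann weighting, no correlated dynamics
between frames.  Passing tests therefore demonstrate that the analysis
stack measures what is present in the coordinates — not that the
generator's ensembles resemble real peptide thermodynamics.

## Geometry engine

Superposition is weighted Kabsch via SVD with the determinant correction
(reflections excluded); it is checked against an independent quaternion
(Horn) oracle at 1e-9.  RMSF uses two passes of mean-structure alignment
(align to the first frame, re-align to the running mean) and reports
per-atom values; the per-residue profile is the Cα RMSF, the standard
reporting convention.  The gyration tensor is mass-weighted by default
(switchable); eigenvalues are sorted descending and `trace = R_g²` holds
exactly.  Anisotropy is reported in the 0 = linear chain … 1 = fully
symmetric convention, b = (λ₂+λ₃)/(2λ₁), which satisfies both limits; the
more common relative shape anisotropy κ² is exported alongside it since
the two conventions run in opposite directions.  Dihedrals follow the
IUPAC sign convention; ring geometry uses least-squares plane fits with
the interplanar angle folded to [0°, 90°].

Harmonic metal-site energies are E = k(r−r₀)² and k(θ−θ₀)², with the
angle force constant interpreted per rad² (a flag switches to per deg²):
printed magnitudes of 150–170 are physically plausible only on the rad²
scale.  The bundled Pt(II) parameter set: bonds [r₀, k] = [2.06, 107]
(Pt–N_phen) and [2.05, 127] (Pt–N_His); angles [81, 169], [89, 150],
[95, 158], [176, 167] for the four N–Pt–N combinations; nonbonded charge
+0.027 e, ε 0.0031 kcal/mol, σ 1.266 Å.

## Secondary structure

The Kabsch–Sander algorithm is implemented from scratch.  Amide hydrogens
are reconstructed at 1.01 Å opposite the bisector of the N's two backbone
bonds; chain-start and proline donors are excluded.  The electrostatic
energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol defines
a bond at E < −0.5, with a Cα-distance prescreen at 9 Å and |i−j| ≥ 2.
n-turns (n = 3, 4, 5) come from i+n→i bonds; two consecutive turns make a
minimal helix (G/H/I).  Bridges follow the parallel/antiparallel bond
patterns; chained bridges form ladders (E), isolated ones B.  T marks
turn-covered residues, S bends (Cα(i−2)–Cα(i)–Cα(i+2) kink > 70°).  Label
precedence on collision: H > E/B > G > I > T > S.  β-bulge merging, the
chirality column and ladder lettering are not implemented.  Grouped
summaries combine H+G+I (helix), E+B (sheet), T+S+C (other).  On synthetic
ensembles the assignment agrees ≥95 % per residue with an established DSSP
implementation (exactly, in the cases tested).

## Interaction detection

Hydrogen bonds: donors are backbone N (minus chain starts and Pro) and the
usual side-chain N/O/S donors; acceptors backbone O/OXT plus side-chain
carboxylate/amide/hydroxyl oxygens, His ring nitrogens and Met S.  For sp2
donors the H is reconstructed from *chemical* connectivity (fixed partner
tables per residue type — robust in strained synthetic frames where
distance-based neighbour detection can be fooled); for rotatable donors
(Lys NH₃⁺, hydroxyls, Cys SH, the N-terminal amine) the H orientation is
undetermined without explicit protons and only the distance criterion
applies.  Defaults: 3.0 Å heavy donor–acceptor, 135° D–H···A; both are
arguments and CLI flags.

Salt bridges: acidic oxygens are Asp/Glu carboxylates plus the C-terminal
carboxylate; basic nitrogens Lys Nζ, Arg Nε/Nη and the free N-terminal
amine; His is not treated as charged (neutral or metal-coordinated at
physiological pH).  A pair counts in a frame when any O–N distance is
below 3.2 Å.

Ligand contacts are reported two ways, because the two conventions answer
different questions: a Cα/Cβ/Cγ-to-ligand-carbon minimum-distance series
(mean ± SD) for side-chain proximity, and an any-heavy-atom minimum for
the <5 Å contact fraction.  Stacking reports, per frame, the minimum
centroid distance over all peptide-ring × ligand-ring pairs (all three
phenanthroline rings are enumerated) and the geometry of the global
closest-contact frame; a stacking *occupancy* additionally requires
centroid distance ≤ 4.5 Å and interplanar angle ≤ 30°.

## Clustering and Ramachandran regions

Pairwise backbone RMSD (every pair superposed independently) feeds classic
DBSCAN: core points have ≥ MinPoints neighbours (self included) within ε;
clusters grow by density reachability; border points join the first
cluster that reaches them in scan order (documented because label-stability
tests depend on it); the rest is noise.  ε is interpreted in Å of backbone
RMSD — RMSD is the metric, Å its unit — with defaults ε = 0.8, MinPoints =
5.  Representatives are medoids (minimum summed intra-cluster distance,
ties to the lowest frame index).  Ramachandran regions are assigned by the
nearest named centre within a 30° Chebyshev radius with angular
wrap-around: αR (−60, −40), PPII (−75, 150), β (−150, 160), γ′ (−80, 80),
and αL (+60, +40) — the αL centre is the standard convention, chosen here
since only "left-handed helical" is constrained.

## Replica-exchange utilities

Temperature ladders are geometric over 270–615 K (T_i = T_min·(T_max/
T_min)^(i/(n−1))); production ladders from heat-capacity-aware generators
will differ, and are accepted as explicit inputs wherever a ladder is
consumed (e.g. the 299.3 K / 304.4 K room-temperature replicas of the 10-
and 16-replica studies are inputs, not regenerated).  The Metropolis swap
probability min(1, exp[(β_i−β_j)(E_i−E_j)]) satisfies detailed balance
exactly and, for exponential (1-D harmonic) energy distributions, has the
closed-form acceptance 2β_hot/(β_cold+β_hot) used as a simulation oracle.
Exchange logs are plain text (`attempt i j accepted`); the overall
acceptance equals the attempt-weighted mean of per-pair acceptances.
Whether a published "exchange frequency" is an attempt-acceptance rate or
a per-frame swap fraction can be ambiguous — both statistics are emitted.

## Study conditions of the analysis scripts

The synthetic study (analysis/02…05) uses a 500-frame Aβ16 ensemble, 40 %
α-helical / 60 % coil frames, 0.12 Å coordinate jitter, seed 2019, with
the three hallmark interactions injected at their observed
room-temperature occupancies: Glu3–Arg5 at 76 %, His14 Nδ–H→Glu11 O at
34 %, Tyr10 stacking at (3.55 Å, 0.18°) in 35 % of frames.  Clustering
runs on a 167-frame stride of that ensemble; problem sizes throughout
(500 frames, ≤16 residues) are chosen so the whole chain of analyses is a
desk-scale computation.

## Known limitations

- Side chains have a single fixed rotamer; χ-angle statistics, rotamer
  entropy and side-chain packing are out of scope.
- The generator produces uncorrelated frames; nothing time-dependent
  (autocorrelations, transition counts) is meaningful on its output.
- DSSP omits β-bulges; sheets built from two idealized strands are flat
  (no twist).
- Rotatable-donor hydrogen bonds are distance-only; with explicit-proton
  inputs the angle test would apply everywhere.
- The PDB writer emits single-character chain IDs and ≤9999 residue
  numbers; very large systems are out of scope.
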