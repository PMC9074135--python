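"""Synthetic peptide/ligand conformers and labelled ensembles.

Every analysis stage in this package is validated against constructed inputs
with known ground truth: ideal-geometry peptides built residue by residue
from backbone internal coordinates at requested (φ, ψ), an idealized planar
1,10-phenanthroline (optionally with its coordinated Pt), π-stacked poses at
controlled centroid distance and interplanar angle, ensembles mixing
conformer classes at exact fractions, injected salt-bridge / hydrogen-bond /
stacking contacts at exact occupancies, and synthetic replica-exchange logs
with exact acceptance fractions.

The peptide builder places backbone N/CA/C/O by the natural-extension
(NeRF) construction using standard internal coordinates (N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å, ω = 180°); side chains are a single fixed
rotamer per residue type taken from the Chemical Component Dictionary ideal
coordinates (heavy atoms only), attached by superposing the template's
N/CA/C onto the built backbone.  All generators are deterministic given
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .structure_io import (
    AA_1TO3,
    ATOMIC_MASSES,
    AtomRecord,
    Frame,
    Residue,
    Topology,
    Trajectory,
    ring_groups,
)
from .geometry import kabsch_superpose, plane_fit

__all__ = [
    "PhiPsiTemplate",
    "TEMPLATES",
    "EnsembleSpec",
    "Injection",
    "GroundTruth",
    "build_peptide",
    "build_phenanthroline",
    "pose_ligand_stack",
    "build_beta_sheet",
    "compose_ensemble",
    "synth_exchange_log",
]


@dataclass(frozen=True)
class PhiPsiTemplate:
    name: str
    phi: float
    psi: float

    def __post_init__(self):
        for a in (self.phi, self.psi):
            if not (-180.0 < a <= 180.0):
                raise ValueError("angles must lie in (−180, 180]")


# Named backbone templates.  The α-helix and polyproline-II/β basins sit at
# their customary Ramachandran centres; the 3,10-helix uses standard ideal
# values since only its basin membership matters here.
TEMPLATES = {
    "alpha": PhiPsiTemplate("alpha", -60.0, -40.0),
    "three_ten": PhiPsiTemplate("three_ten", -49.0, -26.0),
    "beta": PhiPsiTemplate("beta", -150.0, 160.0),
    "ppii": PhiPsiTemplate("ppii", -75.0, 150.0),
    "extended": PhiPsiTemplate("extended", 180.0, 180.0),
}

# φ/ψ basins a disordered "coil" frame draws from, weighted toward the
# broad β/PPII region as in coil libraries; jittered ±25° per residue.
_COIL_BASINS = [(-150.0, 160.0), (-75.0, 150.0), (-90.0, 0.0),
                (-140.0, 60.0), (60.0, 40.0)]
_COIL_WEIGHTS = np.array([0.35, 0.30, 0.15, 0.12, 0.08])


# ---------------------------------------------------------------------------
# internal-coordinate machinery

def _place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: atom bonded to c, with angle b-c-d and torsion a-b-c-d."""
    angle = np.deg2rad(angle)
    torsion = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        -bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 109.47, 116.2, 120.8


@lru_cache(maxsize=None)
def _sidechain_template(resname: str):
    """Heavy-atom side-chain template (names, elements, coords, backbone ref).

    Ideal coordinates from the bundled Chemical Component Dictionary; one
    fixed rotamer per residue type, deterministic across calls.
    """
    import biotite.structure.info as info

    res = info.residue(resname)
    names = list(res.atom_name)
    ref = {}
    side = []
    for j, nm in enumerate(names):
        if res.element[j] == "H":
            continue
        if nm in ("N", "CA", "C"):
            ref[nm] = np.array(res.coord[j], dtype=float)
        elif nm in ("O", "OXT"):
            continue
        else:
            side.append((nm, res.element[j], np.array(res.coord[j], dtype=float)))
    if set(ref) != {"N", "CA", "C"}:
        raise ValueError(f"CCD template for {resname} lacks backbone atoms")
    return ref, side


def build_peptide(
    sequence: str,
    phi_psi,
    chain_id: str = "A",
    first_residue: int = 1,
) -> tuple[Topology, Frame]:
    """Build an all-heavy-atom peptide at prescribed backbone dihedrals.

    ``phi_psi`` is one (φ, ψ) pair per residue (a single pair or a named
    template from :data:`TEMPLATES` is broadcast).  φ of the first residue
    and ψ of the last are termini defaults and do not affect the build.  The
    measured φ/ψ of the returned frame equal the request to 1e-6°.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty sequence")
    for ch in sequence:
        if ch not in AA_1TO3:
            raise ValueError(f"unknown residue letter {ch!r}")
    n_res = len(sequence)
    if isinstance(phi_psi, str):
        t = TEMPLATES[phi_psi]
        phi_psi = [(t.phi, t.psi)] * n_res
    elif isinstance(phi_psi, PhiPsiTemplate):
        phi_psi = [(phi_psi.phi, phi_psi.psi)] * n_res
    phi_psi = [(float(p), float(s)) for p, s in phi_psi]
    if len(phi_psi) != n_res:
        raise ValueError("need one (phi, psi) pair per residue")

    # backbone via NeRF
    bbN = [np.array([0.0, 0.0, 0.0])]
    bbCA = [np.array([_B_N_CA, 0.0, 0.0])]
    dummy = np.array([0.0, -1.0, 0.0])
    bbC = [_place(dummy, bbN[0], bbCA[0], _B_CA_C, _A_N_CA_C, 0.0)]
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        phi_i = phi_psi[i][0]
        N = _place(bbN[i - 1], bbCA[i - 1], bbC[i - 1], _B_C_N, _A_CA_C_N, psi_prev)
        CA = _place(bbCA[i - 1], bbC[i - 1], N, _B_N_CA, _A_C_N_CA, 180.0)  # ω
        C = _place(bbC[i - 1], N, CA, _B_CA_C, _A_N_CA_C, phi_i)
        bbN.append(N)
        bbCA.append(CA)
        bbC.append(C)
    bbO = [
        _place(bbN[i], bbCA[i], bbC[i], _B_C_O, _A_CA_C_O, phi_psi[i][1] + 180.0)
        for i in range(n_res)
    ]
    oxt = _place(bbN[-1], bbCA[-1], bbC[-1], 1.25, _A_CA_C_O, phi_psi[-1][1])

    atoms: list[AtomRecord] = []
    residues: list[Residue] = []
    coords: list[np.ndarray] = []
    serial = 1
    for i, letter in enumerate(sequence):
        resname = AA_1TO3[letter]
        resid = first_residue + i
        start = len(atoms)
        ref, side = _sidechain_template(resname)
        sup = kabsch_superpose(
            np.array([ref["N"], ref["CA"], ref["C"]]),
            np.array([bbN[i], bbCA[i], bbC[i]]),
        )
        placed = [("N", "N", bbN[i]), ("CA", "C", bbCA[i]),
                  ("C", "C", bbC[i]), ("O", "O", bbO[i])]
        placed += [(nm, el, xyz @ sup.rotation.T + sup.translation)
                   for nm, el, xyz in side]
        if i == n_res - 1:
            placed.append(("OXT", "O", oxt))
        for nm, el, xyz in placed:
            atoms.append(AtomRecord(
                serial=serial, name=nm, element=el, residue_index=resid,
                residue_name=resname, chain_id=chain_id,
                mass=ATOMIC_MASSES[el],
            ))
            coords.append(xyz)
            serial += 1
        residues.append(Residue(resid, resname, chain_id, start, len(atoms)))

    top = Topology(atoms=atoms, residues=residues)
    return top, Frame(np.array(coords))


# ---------------------------------------------------------------------------
# phenanthroline

def build_phenanthroline(
    include_platinum: bool = False,
    bond_length: float = 1.40,
) -> tuple[Topology, Frame]:
    """Idealized planar 1,10-phenanthroline (12 C + 2 N heavy atoms).

    The three fused six-membered rings are laid out on an exact hexagonal
    lattice (all aromatic bonds = ``bond_length``), so planarity is exact.
    The chelating nitrogens occupy the bay positions of the two outer rings.
    With ``include_platinum`` a Pt atom is added in-plane, equidistant
    (2.06 Å) from both nitrogens — the mass-weighted Rg of that fragment is
    what trajectory tools report as "the size of the ligand" in the complex.
    """
    a = bond_length
    s3 = np.sqrt(3.0)
    c1 = np.array([0.0, 0.0, 0.0])
    c2 = c1 + a * s3 * np.array([1.0, 0.0, 0.0])
    c3 = c2 + a * s3 * np.array([0.5, 0.5 * s3, 0.0])  # angular (phenanthrene) fusion
    pts: list[np.ndarray] = []
    ring_members: list[set[int]] = []
    for c in (c1, c2, c3):
        members = set()
        for k in range(6):
            ang = np.deg2rad(30 + 60 * k)
            p = c + a * np.array([np.cos(ang), np.sin(ang), 0.0])
            for j, q in enumerate(pts):
                if np.linalg.norm(p - q) < 1e-6:
                    members.add(j)
                    break
            else:
                pts.append(p)
                members.add(len(pts) - 1)
        ring_members.append(members)
    assert len(pts) == 14

    # Chelating N: the closest cross pair between atoms exclusive to the two
    # outer rings — the bay positions facing each other.
    only1 = sorted(ring_members[0] - ring_members[1] - ring_members[2])
    only3 = sorted(ring_members[2] - ring_members[0] - ring_members[1])
    n_a, n_b = min(
        ((i, j) for i in only1 for j in only3),
        key=lambda ij: np.linalg.norm(pts[ij[0]] - pts[ij[1]]),
    )

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = 1
    c_count = 0
    for j, p in enumerate(pts):
        if j == n_a:
            nm, el = "N1", "N"
        elif j == n_b:
            nm, el = "N10", "N"
        else:
            c_count += 1
            nm, el = f"C{c_count}", "C"
        atoms.append(AtomRecord(serial, nm, el, 1, "PHN", "L",
                                ATOMIC_MASSES[el], is_ligand=True))
        coords.append(p)
        serial += 1
    residues = [Residue(1, "PHN", "L", 0, 14, is_ligand=True)]

    if include_platinum:
        na, nb = coords[n_a], coords[n_b]
        mid = 0.5 * (na + nb)
        half = 0.5 * np.linalg.norm(na - nb)
        h = np.sqrt(max(2.06 ** 2 - half ** 2, 0.0))
        centroid = np.mean(coords, axis=0)
        u = mid - centroid
        u /= np.linalg.norm(u)
        atoms.append(AtomRecord(serial, "PT", "PT", 2, "PT", "L",
                                ATOMIC_MASSES["PT"], is_ligand=True))
        coords.append(mid + h * u)
        residues.append(Residue(2, "PT", "L", 14, 15, is_ligand=True))

    top = Topology(atoms=atoms, residues=residues)
    frame = Frame(np.array(coords))
    top._ligand_reference_coords = frame.coordinates  # for ring detection
    return top, frame


# ---------------------------------------------------------------------------
# ligand posing

def _merge(top_a: Topology, frame_a: Frame,
           top_b: Topology, frame_b: Frame) -> tuple[Topology, Frame]:
    """Concatenate two systems into one topology/frame (serials renumbered)."""
    atoms: list[AtomRecord] = []
    residues: list[Residue] = []
    serial = 1
    offset = top_a.n_atoms
    for a in top_a.atoms:
        atoms.append(AtomRecord(serial, a.name, a.element, a.residue_index,
                                a.residue_name, a.chain_id, a.mass, a.is_ligand))
        serial += 1
    for a in top_b.atoms:
        atoms.append(AtomRecord(serial, a.name, a.element, a.residue_index,
                                a.residue_name, a.chain_id, a.mass, a.is_ligand))
        serial += 1
    residues.extend(top_a.residues)
    for r in top_b.residues:
        residues.append(Residue(r.index, r.name, r.chain_id,
                                r.atom_start + offset, r.atom_stop + offset,
                                r.is_ligand))
    top = Topology(atoms=atoms, residues=residues)
    frame = Frame(np.vstack([frame_a.coordinates, frame_b.coordinates]))
    if getattr(top_b, "_ligand_reference_coords", None) is not None:
        ref = np.full((top.n_atoms, 3), np.nan)
        ref[offset:] = frame.coordinates[offset:]
        top._ligand_reference_coords = frame.coordinates
    return top, frame


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector u to unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.clip(u @ v, -1.0, 1.0))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate π about any axis perpendicular to u
        p = np.array([1.0, 0.0, 0.0])
        if abs(u @ p) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, p)
        axis /= np.linalg.norm(axis)
        return _axis_rotation(axis, np.pi)
    axis /= s
    return _axis_rotation(axis, np.arctan2(s, c))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def pose_ligand_stack(
    peptide_top: Topology,
    peptide_frame: Frame,
    ring_selection: str,
    centroid_distance: float,
    interplanar_angle: float,
) -> tuple[Topology, Frame]:
    """Pose phenanthroline π-stacked over a peptide aromatic ring.

    The ligand's central-ring centroid is placed at ``centroid_distance`` Å
    from the peptide ring centroid along the peptide ring normal, with the
    ligand plane tilted by ``interplanar_angle`` degrees.  The measured
    geometry of the combined frame reproduces the request to 1e-3.
    """
    if centroid_distance <= 0:
        raise ValueError("centroid distance must be positive")
    rings = ring_groups(peptide_top, ring_selection)
    ring = rings[0]
    cen, normal = plane_fit(peptide_frame.coordinates[ring])

    lig_top, lig_frame = build_phenanthroline()
    lig_rings = ring_groups(lig_top, "phen")
    # central ring: shares atoms with both others
    central = max(lig_rings, key=lambda r: sum(len(set(r) & set(o))
                                               for o in lig_rings if o is not r))
    lcen, lnormal = plane_fit(lig_frame.coordinates[central])

    X = lig_frame.coordinates - lcen
    R1 = _rotation_between(lnormal, normal)
    X = X @ R1.T
    if interplanar_angle:
        # tilt about an in-plane axis through the central-ring centroid
        axis = np.cross(normal, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(normal, np.array([0.0, 1.0, 0.0]))
        axis /= np.linalg.norm(axis)
        X = X @ _axis_rotation(axis, np.deg2rad(interplanar_angle)).T
    X = X + cen + centroid_distance * normal
    posed = Frame(X)
    lig_top._ligand_reference_coords = X
    return _merge(peptide_top, peptide_frame, lig_top, posed)


# ---------------------------------------------------------------------------
# two-strand β-sheets

def build_beta_sheet(
    sequence: str = "VEVEVE",
    sense: str = "antiparallel",
    n_residues: int | None = None,
) -> tuple[Topology, Frame]:
    """Construct an idealized two-strand β-sheet (one chain per strand).

    The first strand is built at β-strand dihedrals (−140°, 135°); the
    second is a rigid copy placed alongside it, its placement refined by a
    deterministic grid search that maximizes the number of inter-strand
    backbone hydrogen bonds under the Kabsch–Sander energy criterion.
    """
    if n_residues is not None:
        sequence = (sequence * n_residues)[:n_residues]
    if sense not in ("parallel", "antiparallel"):
        raise ValueError("sense must be 'parallel' or 'antiparallel'")
    strand = (-139.0, 135.0) if sense == "antiparallel" else (-119.0, 113.0)
    pp = [strand] * len(sequence)
    top_a, frame_a = build_peptide(sequence, pp, chain_id="A", first_residue=1)
    top_b, frame_b = build_peptide(sequence, pp, chain_id="B",
                                   first_residue=len(sequence) + 1)

    ca_a = np.array([frame_a.coordinates[top_a.find_atom(r.index, "CA")]
                     for r in top_a.residues])
    axis = ca_a[-1] - ca_a[0]
    axis /= np.linalg.norm(axis)
    cen = ca_a.mean(axis=0)
    # strand plane normal: perpendicular to axis, least-squares over CA
    _, _, Vt = np.linalg.svd(ca_a - cen)
    side = np.cross(axis, Vt[2])
    side /= np.linalg.norm(side)

    Xb0 = frame_b.coordinates - frame_b.coordinates.mean(axis=0)
    if sense == "antiparallel":
        R = _axis_rotation(side, np.pi)       # flips chain direction, keeps side
    else:
        R = np.eye(3)
    Xb0 = Xb0 @ R.T

    from .dssp import _ks_interchain_bond_count  # deterministic scorer

    best = None
    for dist in np.arange(4.2, 5.6, 0.1):
        for shift in np.arange(-3.5, 3.6, 0.25):
            for lift in (np.arange(-1.0, 1.01, 0.5)):
                Xb = Xb0 + cen + dist * side + shift * axis + lift * Vt[2]
                nb = _ks_interchain_bond_count(top_a, frame_a.coordinates,
                                               top_b, Xb)
                key = (nb, -abs(shift))
                if best is None or key > best[0]:
                    best = (key, Xb)
    Xb = best[1]
    # local refinement
    base = Xb.copy()
    for dd in np.arange(-0.3, 0.31, 0.05):
        for ds in np.arange(-0.4, 0.41, 0.05):
            Xb_try = base + dd * side + ds * axis
            nb = _ks_interchain_bond_count(top_a, frame_a.coordinates,
                                           top_b, Xb_try)
            key = (nb, -abs(ds))
            if key > best[0]:
                best = (key, Xb_try)
    return _merge(top_a, frame_a, top_b, Frame(best[1]))


# ---------------------------------------------------------------------------
# composed ensembles

@dataclass(frozen=True)
class Injection:
    """A contact injected into a controlled fraction of frames.

    kinds:
      ``salt_bridge``  — acidic residue's closest carboxylate O placed at
                         ``distance`` Å from the basic residue's N.
      ``hbond``        — ``donor_atom`` of ``residue_a`` placed so its
                         (reconstructed) H points at ``acceptor_atom`` of
                         ``residue_b`` at ``distance`` Å (donor→acceptor).
      ``stacking``     — phenanthroline posed over ``residue_a``'s ring at
                         (``distance`` Å, ``angle``°); parked 25 Å away in
                         non-injected frames.
    """
    kind: str
    residue_a: int
    residue_b: int = 0
    distance: float = 3.0
    angle: float = 0.0
    occupancy: float = 1.0
    donor_atom: str = ""
    acceptor_atom: str = ""

    def __post_init__(self):
        if self.kind not in ("salt_bridge", "hbond", "stacking"):
            raise ValueError(f"unknown injection kind {self.kind!r}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must be in [0, 1]")


@dataclass
class EnsembleSpec:
    sequence: str
    n_frames: int
    class_fractions: dict
    noise_sigma: float = 0.0
    seed: int = 0
    injections: list = field(default_factory=list)

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


@dataclass
class GroundTruth:
    classes: list                      # per-frame conformer-class name
    injected: dict                     # injection key → per-frame bool array


def _class_counts(fractions: dict, n: int) -> dict:
    """Exact frame counts per class: round(f*n) with largest-remainder fixup."""
    raw = {k: fractions[k] * n for k in fractions}
    counts = {k: int(round(v)) for k, v in raw.items()}
    diff = n - sum(counts.values())
    if diff != 0:
        order = sorted(raw, key=lambda k: (raw[k] - np.floor(raw[k])), reverse=diff > 0)
        for k in order[:abs(diff)]:
            counts[k] += 1 if diff > 0 else -1
    return counts


def _coil_phipsi(n_res: int, rng: np.random.Generator) -> list:
    basins = rng.choice(len(_COIL_BASINS), size=n_res,
                        p=_COIL_WEIGHTS / _COIL_WEIGHTS.sum())
    out = []
    for b in basins:
        phi, psi = _COIL_BASINS[b]
        phi += rng.uniform(-25, 25)
        psi += rng.uniform(-25, 25)
        out.append((((phi + 180) % 360) - 180, ((psi + 180) % 360) - 180))
    return out


def compose_ensemble(spec: EnsembleSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate a labelled trajectory from an :class:`EnsembleSpec`.

    Frames are built from templates drawn at exact per-class counts
    (seeded order); i.i.d. Gaussian noise of ``noise_sigma`` Å is added per
    coordinate; each injection is realized in exactly
    ``round(occupancy × n_frames)`` frames and verified absent elsewhere
    (offending geometry is re-posed after noise so ground-truth occupancies
    are exact).  Identical seeds give identical output.
    """
    from . import interactions as inter

    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec.class_fractions, spec.n_frames)
    labels = [k for k, c in counts.items() for _ in range(c)]
    rng.shuffle(labels)

    has_stack = any(inj.kind == "stacking" for inj in spec.injections)
    stack_inj = next((inj for inj in spec.injections if inj.kind == "stacking"), None)

    inj_frames: dict[str, np.ndarray] = {}
    for inj in spec.injections:
        key = _injection_key(inj)
        n_on = int(round(inj.occupancy * spec.n_frames))
        chosen = rng.permutation(spec.n_frames)[:n_on]
        flags = np.zeros(spec.n_frames, dtype=bool)
        flags[chosen] = True
        inj_frames[key] = flags

    frames: list[Frame] = []
    topology: Topology | None = None
    for k in range(spec.n_frames):
        cls = labels[k]
        if cls == "coil":
            pp = _coil_phipsi(len(spec.sequence), rng)
        elif cls in TEMPLATES:
            t = TEMPLATES[cls]
            pp = [(t.phi, t.psi)] * len(spec.sequence)
        else:
            raise ValueError(f"unknown conformer class {cls!r}")
        top, frame = build_peptide(spec.sequence, pp)

        if has_stack:
            on = inj_frames[_injection_key(stack_inj)][k]
            d = stack_inj.distance if on else 25.0
            ang = stack_inj.angle if on else 0.0
            top, frame = pose_ligand_stack(
                top, frame, f"ring({_restoken(top, stack_inj.residue_a)})", d, ang)
        if topology is None:
            topology = top

        X = frame.coordinates
        if spec.noise_sigma > 0:
            X = X + rng.normal(0.0, spec.noise_sigma, X.shape)

        for inj in spec.injections:
            on = inj_frames[_injection_key(inj)][k]
            if inj.kind == "salt_bridge":
                X = _apply_salt_bridge(top, X, inj, on)
            elif inj.kind == "hbond":
                X = _apply_hbond(top, X, inj, on)
            elif inj.kind == "stacking" and on and spec.noise_sigma > 0:
                # noise perturbs the posed geometry; re-pose the rigid ligand
                X = _repose_ligand(top, X, frame.coordinates)
        frames.append(Frame(X, frame_index=k))

    traj = Trajectory(topology=topology, frames=frames)
    truth = GroundTruth(classes=labels, injected=inj_frames)
    return traj, truth


def _injection_key(inj: Injection) -> str:
    if inj.kind == "stacking":
        return f"stacking:{inj.residue_a}"
    return f"{inj.kind}:{inj.residue_a}-{inj.residue_b}"


def _restoken(top: Topology, resid: int) -> str:
    for r in top.residues:
        if r.index == resid:
            return f"{r.name}{r.index}"
    raise ValueError(f"no residue {resid}")


def _sidechain_indices(top: Topology, resid: int) -> list[int]:
    out = []
    for r in top.residues:
        if r.index == resid:
            for i in r.atom_indices():
                if top.atoms[i].name not in ("N", "CA", "C", "O", "OXT"):
                    out.append(i)
    if not out:
        raise ValueError(f"residue {resid} has no side-chain atoms")
    return out


def _apply_salt_bridge(top: Topology, X: np.ndarray, inj: Injection,
                       on: bool) -> np.ndarray:
    from .interactions import acidic_oxygens, basic_nitrogens

    o_idx = [i for i in acidic_oxygens(top)
             if top.atoms[i].residue_index == inj.residue_a]
    n_idx = [i for i in basic_nitrogens(top)
             if top.atoms[i].residue_index == inj.residue_b]
    if not o_idx or not n_idx:
        raise ValueError(
            f"salt-bridge injection infeasible: residues {inj.residue_a}"
            f"/{inj.residue_b} lack charged-group atoms")
    d = np.linalg.norm(X[o_idx][:, None, :] - X[n_idx][None, :, :], axis=2)
    ii, jj = np.unravel_index(np.argmin(d), d.shape)
    o, n = o_idx[ii], n_idx[jj]
    target = inj.distance if on else max(2.0 * 3.2, d[ii, jj])
    if (on and abs(d[ii, jj] - inj.distance) < 1e-9) or (not on and d[ii, jj] >= 3.4):
        return X
    u = X[o] - X[n]
    u /= np.linalg.norm(u)
    shift = (X[n] + target * u) - X[o]
    X = X.copy()
    X[_sidechain_indices(top, inj.residue_a)] += shift
    return X


def _apply_hbond(top: Topology, X: np.ndarray, inj: Injection,
                 on: bool) -> np.ndarray:
    from .interactions import reconstruct_donor_h

    d_i = top.find_atom(inj.residue_a, inj.donor_atom)
    a_i = top.find_atom(inj.residue_b, inj.acceptor_atom)
    if d_i < 0 or a_i < 0:
        raise ValueError("hbond injection: donor/acceptor atom not found")
    sidechain = _sidechain_indices(top, inj.residue_a)
    if d_i not in sidechain:
        raise ValueError("hbond injection supports side-chain donors only")
    r = np.linalg.norm(X[d_i] - X[a_i])
    X = X.copy()
    if on:
        # Place the donor so the donor→acceptor axis runs along the donor's
        # reconstructed H direction.  Translating the side chain can change
        # the donor's apparent covalent neighbourhood (and hence the
        # reconstructed H), so iterate to self-consistency.
        for _ in range(8):
            h = reconstruct_donor_h(top, X, d_i)
            if h is None:
                u = (X[a_i] - X[d_i])
                u /= np.linalg.norm(u)
            else:
                u = h[0] - X[d_i]
                u /= np.linalg.norm(u)
            shift = (X[a_i] - inj.distance * u) - X[d_i]
            if np.linalg.norm(shift) < 1e-9:
                break
            X[sidechain] += shift
    elif r < 4.0:
        u = (X[d_i] - X[a_i]) / r
        X[sidechain] += (X[a_i] + 8.0 * u) - X[d_i]
    return X


def _repose_ligand(top: Topology, X: np.ndarray, clean: np.ndarray) -> np.ndarray:
    lig = [i for i, a in enumerate(top.atoms) if a.is_ligand]
    X = X.copy()
    X[lig] = clean[lig]
    return X


# ---------------------------------------------------------------------------
# synthetic replica-exchange logs

def synth_exchange_log(
    n_replicas: int,
    n_attempts: int,
    acceptance: float,
    seed: int = 0,
):
    """Synthetic neighbour-exchange log with an exact acceptance fraction.

    Attempts alternate between the even pair set (0,1),(2,3),… and the odd
    set (1,2),(3,4),…; exactly ``round(acceptance × n_attempts)`` attempts
    are accepted, their positions shuffled deterministically by seed.
    """
    from .remd import ExchangeLog, ExchangeRecord

    if n_replicas < 2:
        raise ValueError("need at least two replicas")
    if not (0.0 <= acceptance <= 1.0):
        raise ValueError("acceptance must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_acc = int(round(acceptance * n_attempts))
    flags = np.zeros(n_attempts, dtype=bool)
    flags[rng.permutation(n_attempts)[:n_acc]] = True
    records = []
    sweep = 0
    k = 0
    while k < n_attempts:
        parity = sweep % 2
        pairs = [(i, i + 1) for i in range(parity, n_replicas - 1, 2)]
        if not pairs:
            pairs = [(i, i + 1) for i in range(0, n_replicas - 1, 2)]
        for i, j in pairs:
            if k >= n_attempts:
                break
            records.append(ExchangeRecord(attempt=k, replica_i=i, replica_j=j,
                                          accepted=bool(flags[k])))
            k += 1
        sweep += 1
    return ExchangeLog(records=records, n_replicas=n_replicas)
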