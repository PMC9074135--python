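"""Superposition, deviation/fluctuation statistics, gyration-tensor shape
descriptors, dihedral angles, ring geometry, and harmonic metal-site energies.

Conventions
-----------
* RMSD uses the Kabsch least-squares superposition (proper rotation only).
* The gyration tensor is S = Σ w_i (x_i−x̄)(x_i−x̄)ᵀ / Σ w_i with weights w
  equal to atomic masses by default; its eigenvalues are reported sorted
  descending, and trace(S) = Rg² exactly.
* Shape anisotropy follows the convention in which 0 denotes an ideal linear
  chain and 1 a fully symmetric mass distribution: b = (λ2+λ3)/(2λ1).  The
  more common relative shape anisotropy κ² (1 = rod, 0 = sphere) is exported
  alongside it.
* Dihedrals use the IUPAC sign convention; φ(i) = C(i−1)–N(i)–CA(i)–C(i) and
  ψ(i) = N(i)–CA(i)–C(i)–N(i+1), undefined at chain termini.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import Frame, Topology, Trajectory, select

__all__ = [
    "SuperpositionResult",
    "GyrationResult",
    "MetalSiteParameters",
    "PT_PHEN_PARAMETERS",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "gyration",
    "shape_series",
    "dihedral",
    "dihedrals",
    "ring_geometry",
    "plane_fit",
    "harmonic_energy",
]


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray        # 3×3 proper orthogonal
    translation: np.ndarray     # Å; x_fit = R @ x_mobile + t
    rmsd: float                 # Å


@dataclass(frozen=True)
class GyrationResult:
    rg: float                   # Å
    eigenvalues: np.ndarray     # Å², sorted descending
    anisotropy: float           # 0 = linear chain ... 1 = fully symmetric
    asphericity: float          # Å²
    kappa2: float               # relative shape anisotropy (1 = rod)


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal weighted rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation R and translation t minimizing the weighted
    RMSD of ``R @ mobile + t`` to ``reference``; reflections are excluded.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    w = np.ones(len(P)) if weights is None else np.asarray(weights, dtype=float)
    wn = w / w.sum()
    pc = wn @ P
    qc = wn @ Q
    H = (P - pc).T @ ((Q - qc) * wn[:, None])
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((wn * (diff ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _resolve_selection(top: Topology, selection) -> np.ndarray:
    if selection is None:
        return np.arange(top.n_atoms)
    if isinstance(selection, str):
        return np.array(select(top, selection), dtype=int)
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    return idx


def rmsd_series(
    traj: Trajectory,
    reference: Frame | np.ndarray | None = None,
    selection="backbone",
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Å) against a fixed reference over a selection.

    The reference defaults to the first frame; with ``fit`` each frame is
    optimally superposed before the deviation is measured, without it the
    raw coordinate deviation is returned.
    """
    idx = _resolve_selection(traj.topology, selection)
    if reference is None:
        ref = traj.frames[0].coordinates[idx]
    elif isinstance(reference, Frame):
        ref = reference.coordinates[idx]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape[0] == traj.topology.n_atoms:
            ref = ref[idx]
    if ref.shape[0] != len(idx):
        raise ValueError("selection atoms missing in reference")
    out = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        x = frame.coordinates[idx]
        if fit:
            out[k] = kabsch_superpose(x, ref).rmsd
        else:
            out[k] = float(np.sqrt(((x - ref) ** 2).sum(axis=1).mean()))
    return out


def rmsf(
    traj: Trajectory,
    selection="calpha",
    align: bool = True,
    n_passes: int = 2,
) -> pd.DataFrame:
    """Per-atom RMS fluctuation about the mean structure (Å).

    With ``align``, all frames are first superposed onto the running mean
    structure of the selection (``n_passes`` refinement passes, starting from
    the first frame).  Returns one row per selected atom with its residue
    index so a per-residue (Cα) profile falls out directly.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    top = traj.topology
    idx = _resolve_selection(top, selection)
    X = traj.coords()[:, idx]                       # (F, n, 3)
    if align:
        ref = X[0]
        for _ in range(n_passes):
            for k in range(X.shape[0]):
                sup = kabsch_superpose(X[k], ref)
                X[k] = X[k] @ sup.rotation.T + sup.translation
            ref = X.mean(axis=0)
    mean = X.mean(axis=0)
    fluct = np.sqrt(((X - mean) ** 2).sum(axis=2).mean(axis=0))
    return pd.DataFrame({
        "atom_index": idx,
        "atom_name": [top.atoms[i].name for i in idx],
        "residue_index": [top.atoms[i].residue_index for i in idx],
        "residue_name": [top.atoms[i].residue_name for i in idx],
        "rmsf": fluct,
    })


def gyration(
    coordinates: np.ndarray,
    masses: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> GyrationResult:
    """Radius of gyration and gyration-tensor shape descriptors.

    ``masses`` is required when ``mass_weighted`` (the default); pass
    ``mass_weighted=False`` for the unweighted (geometric) tensor.
    """
    X = np.asarray(coordinates, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 1:
        raise ValueError("coordinates must be a non-empty (n, 3) array")
    if mass_weighted:
        if masses is None:
            raise ValueError("mass-weighted gyration needs masses")
        w = np.asarray(masses, dtype=float)
    else:
        w = np.ones(X.shape[0])
    wn = w / w.sum()
    c = wn @ X
    d = X - c
    S = (d * wn[:, None]).T @ d
    lam = np.linalg.eigvalsh(S)[::-1]               # descending
    lam = np.clip(lam, 0.0, None)
    rg = float(np.sqrt(lam.sum()))
    l1, l2, l3 = lam
    if l1 <= 0:
        aniso = 0.0
    else:
        aniso = float((l2 + l3) / (2.0 * l1))
    asph = float(l1 - 0.5 * (l2 + l3))
    tr = lam.sum()
    if tr <= 0:
        kappa2 = 0.0
    else:
        kappa2 = float(1.0 - 3.0 * (l1 * l2 + l2 * l3 + l3 * l1) / tr ** 2)
    return GyrationResult(rg=rg, eigenvalues=lam, anisotropy=aniso,
                          asphericity=asph, kappa2=kappa2)


def gyration_of(traj_or_frame, topology: Topology | None = None,
                selection=None, mass_weighted: bool = True) -> GyrationResult:
    """Convenience: gyration of a Frame (with its Topology) over a selection."""
    if isinstance(traj_or_frame, Trajectory):
        top = traj_or_frame.topology
        frame = traj_or_frame.frames[0]
    else:
        frame = traj_or_frame
        top = topology
        if top is None:
            raise ValueError("need a topology for selection/masses")
    idx = _resolve_selection(top, selection)
    return gyration(frame.coordinates[idx], top.masses[idx], mass_weighted)


def shape_series(
    traj: Trajectory,
    selection=None,
    mass_weighted: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame gyration/shape descriptors plus ensemble summary statistics.

    Returns ``(per_frame, summary)`` DataFrames; the summary carries
    mean/SD/min/max per descriptor and a ``prolate`` flag (mean λ1 at least
    three times the mean of λ2, with λ2 ≈ λ3 within a factor of two).
    """
    top = traj.topology
    idx = _resolve_selection(top, selection)
    m = top.masses[idx]
    rows = []
    for k, f in enumerate(traj.frames):
        g = gyration(f.coordinates[idx], m, mass_weighted)
        rows.append((k, g.rg, *g.eigenvalues, g.anisotropy, g.asphericity, g.kappa2))
    per_frame = pd.DataFrame(
        rows, columns=["frame", "rg", "lambda1", "lambda2", "lambda3",
                       "anisotropy", "asphericity", "kappa2"],
    ).set_index("frame")
    summary = per_frame.agg(["mean", "std", "min", "max"])
    l1, l2, l3 = (summary.loc["mean", c] for c in ("lambda1", "lambda2", "lambda3"))
    summary.attrs["prolate"] = bool(l1 >= 3 * l2 and (l3 == 0 or l2 <= 2 * l3))
    return per_frame, summary


# ---------------------------------------------------------------------------
# dihedrals

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, IUPAC convention) of four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    ang = np.degrees(np.arctan2(y, x))
    return float(180.0 if np.isclose(ang, -180.0) else ang)


def dihedrals(traj: Trajectory) -> pd.DataFrame:
    """Backbone φ/ψ table: one row per (frame, residue); NaN at termini.

    Chain breaks (chain-id change or non-consecutive residue numbering with
    a broken C–N bond) terminate φ/ψ continuity like a terminus.
    """
    top = traj.topology
    residues = top.peptide_residues
    names = {}
    for r in residues:
        for i in r.atom_indices():
            names[(r.index, top.atoms[i].name)] = i
    rows = []
    for k, frame in enumerate(traj.frames):
        X = frame.coordinates
        for j, r in enumerate(residues):
            phi = psi = np.nan
            prev_r = residues[j - 1] if j > 0 else None
            next_r = residues[j + 1] if j + 1 < len(residues) else None
            if prev_r is not None and not _contiguous(top, prev_r, r, X):
                prev_r = None
            if next_r is not None and not _contiguous(top, r, next_r, X):
                next_r = None
            try:
                if prev_r is not None:
                    phi = dihedral(X[names[(prev_r.index, "C")]],
                                   X[names[(r.index, "N")]],
                                   X[names[(r.index, "CA")]],
                                   X[names[(r.index, "C")]])
                if next_r is not None:
                    psi = dihedral(X[names[(r.index, "N")]],
                                   X[names[(r.index, "CA")]],
                                   X[names[(r.index, "C")]],
                                   X[names[(next_r.index, "N")]])
            except KeyError as exc:
                raise ValueError(f"missing backbone atom {exc} in residue {r.index}")
            rows.append((k, r.index, r.name, phi, psi))
    return pd.DataFrame(rows, columns=["frame", "residue_index", "residue_name",
                                       "phi", "psi"])


def _contiguous(top: Topology, a, b, X: np.ndarray) -> bool:
    """Sequential peptide-bonded residues (same chain, C–N within 2.5 Å)."""
    if a.chain_id != b.chain_id:
        return False
    ci = top.find_atom(a.index, "C")
    ni = top.find_atom(b.index, "N")
    if ci < 0 or ni < 0:
        return False
    return bool(np.linalg.norm(X[ci] - X[ni]) < 2.5)


# ---------------------------------------------------------------------------
# ring geometry

def plane_fit(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points: returns (centroid, unit normal)."""
    P = np.asarray(points, dtype=float)
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points to fit a plane")
    c = P.mean(axis=0)
    _, s, Vt = np.linalg.svd(P - c)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("points are collinear; no unique plane")
    return c, Vt[2]


def ring_geometry(coordinates: np.ndarray, ring_a, ring_b) -> tuple[float, float]:
    """Centroid distance (Å) and interplanar angle (deg, folded to [0, 90])."""
    X = np.asarray(coordinates, dtype=float)
    ca, na = plane_fit(X[np.asarray(ring_a, dtype=int)])
    cb, nb = plane_fit(X[np.asarray(ring_b, dtype=int)])
    dist = float(np.linalg.norm(ca - cb))
    cosang = abs(float(np.clip(na @ nb, -1.0, 1.0)))
    return dist, float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# harmonic metal-site forcefield terms

@dataclass(frozen=True)
class MetalSiteParameters:
    """Harmonic bond/angle terms and nonbonded parameters for a metal site.

    Bond terms: label → (r0 Å, k kcal·mol⁻¹·Å⁻²), energy k(r−r0)².
    Angle terms: label → (θ0 deg, k kcal·mol⁻¹·rad⁻²), energy k(θ−θ0)² with
    θ−θ0 in radians unless ``angle_k_per_degree`` is set.
    """
    bond_terms: dict
    angle_terms: dict
    charge: float = 0.0             # e
    epsilon: float = 0.0            # kcal/mol
    sigma: float = 0.0              # Å
    angle_k_per_degree: bool = False

    def __post_init__(self):
        for label, (r0, k) in self.bond_terms.items():
            if r0 <= 0 or k <= 0:
                raise ValueError(f"bond term {label}: r0 and k must be positive")
        for label, (t0, k) in self.angle_terms.items():
            if not (0 < t0 <= 180) or k <= 0:
                raise ValueError(f"angle term {label}: θ0 in (0,180], k > 0")


# Pt(II) coordinated to phenanthroline (bidentate) and two His Nε, as
# derived from quantum-mechanical normal-mode fitting of the complex.
PT_PHEN_PARAMETERS = MetalSiteParameters(
    bond_terms={
        "Pt-N_phen": (2.06, 107.0),
        "Pt-N_His": (2.05, 127.0),
    },
    angle_terms={
        "N_phen-Pt-N_phen": (81.0, 169.0),
        "N_His-Pt-N_His": (89.0, 150.0),
        "N_phen-Pt-N_His_cis": (95.0, 158.0),
        "N_phen-Pt-N_His_trans": (176.0, 167.0),
    },
    charge=0.027,
    epsilon=0.0031,
    sigma=1.266,
)


def harmonic_energy(
    params: MetalSiteParameters,
    bonds: dict | None = None,
    angles: dict | None = None,
) -> dict:
    """Evaluate harmonic bond/angle energies for measured geometry.

    ``bonds`` maps term label → measured distance (Å); ``angles`` maps term
    label → measured angle (deg).  Returns per-term energies plus ``total``
    (kcal/mol).  Every measured term must have a parameter entry.
    """
    out: dict[str, float] = {}
    for label, r in (bonds or {}).items():
        if label not in params.bond_terms:
            raise KeyError(f"no bond parameters for {label!r}")
        r0, k = params.bond_terms[label]
        out[label] = k * (r - r0) ** 2
    for label, theta in (angles or {}).items():
        if label not in params.angle_terms:
            raise KeyError(f"no angle parameters for {label!r}")
        t0, k = params.angle_terms[label]
        d = theta - t0
        if not params.angle_k_per_degree:
            d = np.deg2rad(d)
        out[label] = k * d ** 2
    out["total"] = float(sum(out.values()))
    return out
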