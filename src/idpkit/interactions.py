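"""Hydrogen bonds, salt bridges, ligand contacts, π-stacking, contact maps.

All detectors run on heavy-atom-only inputs.  Hydrogen positions needed for
the donor–H···acceptor angle test are reconstructed geometrically for sp2
nitrogens (amide backbone, His/Trp ring NH, Arg guanidinium, Asn/Gln
amides); for rotatable donors (Lys NH3+, Ser/Thr/Tyr hydroxyls, Cys SH,
the N-terminal amine) the hydrogen orientation is undetermined without
explicit protons, so only the distance criterion applies to them.

Definitions (all cutoffs exposed as arguments):

* hydrogen bond — heavy donor→acceptor distance ≤ 3.0 Å and
  D–H···A angle ≥ 135° (when the H direction is determined);
* salt bridge — any O–N distance < 3.2 Å between an acidic oxygen
  (Asp/Glu carboxylate, C-terminal carboxylate) and a basic nitrogen
  (Lys Nζ, Arg Nε/Nη, N-terminal amine);
* stacking contact — ring-centroid distance and interplanar angle from a
  least-squares plane fit, reported for the closest ring pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Topology, Trajectory, ring_groups, ligand_rings_from_frame
from .geometry import ring_geometry

__all__ = [
    "hydrogen_bonds",
    "classify_hbonds",
    "hbond_occupancy",
    "salt_bridges",
    "ligand_contacts",
    "stacking_search",
    "stacking_occupancy",
    "contact_map",
    "acidic_oxygens",
    "basic_nitrogens",
    "reconstruct_donor_h",
]

# side-chain donor/acceptor tables (atom names per residue type)
_SP2_DONORS = {
    "HIS": ("ND1", "NE2"), "HID": ("ND1",), "HIE": ("NE2",), "HIP": ("ND1", "NE2"),
    "TRP": ("NE1",),
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",), "GLN": ("NE2",),
}
_ROTATABLE_DONORS = {
    "LYS": ("NZ",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "CYS": ("SG",),
}
_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",), "GLN": ("OE1",),
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "HID": ("NE2",), "HIE": ("ND1",),
    "MET": ("SD",),
}


def _neighbour_map(top: Topology, X: np.ndarray, idx: int,
                   cutoff: float = 1.8) -> list[int]:
    """Covalent neighbours of an atom within its residue (by distance)."""
    res = top.residue_of_atom(idx)
    out = []
    for i in res.atom_indices():
        d = np.linalg.norm(X[i] - X[idx])
        if i != idx and d < cutoff:
            out.append((d, i))
    # backbone N also bonds the previous residue's C
    if top.atoms[idx].name == "N":
        prev = top.find_atom(res.index - 1, "C")
        if prev >= 0:
            d = np.linalg.norm(X[prev] - X[idx])
            if d < cutoff:
                out.append((d, prev))
    # nearest first: true covalent partners beat incidental close contacts
    return [i for _, i in sorted(out)]


# covalent heavy-atom partners of each sp2 donor, by residue/atom name;
# chemical connectivity is used (not distances) so reconstruction is stable
# even in sterically strained synthetic frames
_DONOR_PARTNERS = {
    ("HIS", "ND1"): ("CG", "CE1"), ("HIS", "NE2"): ("CD2", "CE1"),
    ("HID", "ND1"): ("CG", "CE1"), ("HIE", "NE2"): ("CD2", "CE1"),
    ("HIP", "ND1"): ("CG", "CE1"), ("HIP", "NE2"): ("CD2", "CE1"),
    ("TRP", "NE1"): ("CD1", "CE2"),
    ("ARG", "NE"): ("CD", "CZ"),
    ("ARG", "NH1"): ("CZ",), ("ARG", "NH2"): ("CZ",),
    ("ASN", "ND2"): ("CG",), ("GLN", "NE2"): ("CD",),
}


def reconstruct_donor_h(top: Topology, X: np.ndarray,
                        donor: int) -> np.ndarray | None:
    """Reconstructed H position(s) for an sp2 donor; None if undetermined.

    Two in-plane neighbours → one H opposite their bisector; one neighbour
    (planar NH2/guanidinium) → two H at ±120° in the local sp2 plane.
    Returns an (n_H, 3) array.
    """
    atom = top.atoms[donor]
    res = top.residue_of_atom(donor)
    partners = _DONOR_PARTNERS.get((res.name.upper(), atom.name))
    if partners is not None:
        nbrs = [top.find_atom(res.index, nm) for nm in partners]
        nbrs = [i for i in nbrs if i >= 0]
    elif atom.name == "N":
        prev_c = top.find_atom(res.index - 1, "C")
        if prev_c >= 0 and np.linalg.norm(X[prev_c] - X[donor]) > 2.5:
            prev_c = -1         # chain break: not actually bonded
        ca = top.find_atom(res.index, "CA")
        nbrs = [i for i in (prev_c, ca) if i >= 0]
    else:
        nbrs = _neighbour_map(top, X, donor)
    d = X[donor]
    if len(nbrs) >= 2:
        u = sum((X[n] - d) / np.linalg.norm(X[n] - d) for n in nbrs[:2])
        norm = np.linalg.norm(u)
        if norm < 1e-8:
            return None
        return (d - 1.01 * u / norm)[None, :]
    if len(nbrs) == 1:
        p = nbrs[0]
        gps = [g for g in _neighbour_map(top, X, p) if g != donor]
        if not gps:
            return None
        g = gps[0]
        u = X[p] - d
        u /= np.linalg.norm(u)
        w = X[g] - X[p]
        w -= (w @ u) * u
        nw = np.linalg.norm(w)
        if nw < 1e-8:
            return None
        w /= nw
        # two H at 120° from the donor→parent bond, in the sp2 plane
        out = []
        for sign in (+1.0, -1.0):
            direction = np.cos(np.deg2rad(120.0)) * u + sign * np.sin(np.deg2rad(120.0)) * w
            out.append(d + 1.01 * direction)
        return np.array(out)
    return None


def _donor_list(top: Topology) -> list[tuple[int, bool]]:
    """(atom index, h_determined) for every potential donor heavy atom."""
    out = []
    peptide = top.peptide_residues
    first_res = {}.fromkeys([])
    chain_first = {}
    for r in peptide:
        chain_first.setdefault(r.chain_id, r.index)
    for r in peptide:
        for i in r.atom_indices():
            nm = top.atoms[i].name
            if nm == "N":
                if r.index == chain_first[r.chain_id]:
                    out.append((i, False))      # N-terminal amine: rotatable
                elif r.name.upper() != "PRO":
                    out.append((i, True))
            elif nm in _SP2_DONORS.get(r.name.upper(), ()):
                out.append((i, True))
            elif nm in _ROTATABLE_DONORS.get(r.name.upper(), ()):
                out.append((i, False))
    return out


def _acceptor_list(top: Topology) -> list[int]:
    out = []
    for r in top.peptide_residues:
        for i in r.atom_indices():
            nm = top.atoms[i].name
            if nm in ("O", "OXT") or nm in _ACCEPTORS.get(r.name.upper(), ()):
                out.append(i)
    return out


def hydrogen_bonds(
    traj: Trajectory,
    dist_cutoff: float = 3.0,
    angle_cutoff: float = 135.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect hydrogen bonds in every frame.

    Returns ``(records, per_frame)``: one record per bond occurrence with
    donor/acceptor atoms and residues, distance, angle (NaN when the donor H
    is orientation-free and the angle test is waived), a backbone–backbone
    flag, and the donor-minus-acceptor residue offset; and per-frame count
    statistics.
    """
    top = traj.topology
    donors = _donor_list(top)
    acceptors = _acceptor_list(top)
    if not donors or not acceptors:
        return (pd.DataFrame(), pd.DataFrame({"frame": [], "count": []}))
    acc = np.array(acceptors)
    rows = []
    counts = []
    for k, frame in enumerate(traj.frames):
        X = frame.coordinates
        tree = cKDTree(X[acc])
        n_in_frame = 0
        for d_i, determined in donors:
            d_res = top.residue_of_atom(d_i)
            hs = reconstruct_donor_h(top, X, d_i) if determined else None
            if determined and hs is None:
                determined = False
            for j in tree.query_ball_point(X[d_i], dist_cutoff):
                a_i = int(acc[j])
                a_res = top.residue_of_atom(a_i)
                if a_res.index == d_res.index and a_res.chain_id == d_res.chain_id:
                    continue
                r = float(np.linalg.norm(X[d_i] - X[a_i]))
                angle = np.nan
                if determined:
                    best = -1.0
                    for h in hs:
                        v1 = X[d_i] - h
                        v2 = X[a_i] - h
                        cosa = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        best = max(best, float(np.degrees(np.arccos(np.clip(cosa, -1, 1)))))
                    angle = best
                    if angle < angle_cutoff:
                        continue
                bb = (top.atoms[d_i].name == "N" and
                      top.atoms[a_i].name in ("O", "OXT"))
                rows.append((k, d_i, a_i, d_res.index, a_res.index,
                             top.atoms[d_i].name, top.atoms[a_i].name,
                             r, angle, bb, d_res.index - a_res.index))
                n_in_frame += 1
        counts.append((k, n_in_frame))
    records = pd.DataFrame(rows, columns=[
        "frame", "donor", "acceptor", "donor_residue", "acceptor_residue",
        "donor_name", "acceptor_name", "distance", "angle",
        "backbone_backbone", "sequence_offset"])
    per_frame = pd.DataFrame(counts, columns=["frame", "count"])
    return records, per_frame


def classify_hbonds(records: pd.DataFrame) -> dict:
    """Bin hydrogen bonds: i+3→i, i+4→i, i+5→i, other backbone, side-chain.

    Backbone–backbone bonds are classified by the donor-minus-acceptor
    residue offset (i+4→i is the α-helical pattern, i+3→i the 3,10 pattern,
    i+5→i the π-helical one); anything involving a side chain goes to the
    side-chain bin.
    """
    out = {"i+3->i": 0, "i+4->i": 0, "i+5->i": 0, "other_backbone": 0,
           "side_chain": 0}
    if records.empty:
        return out
    for _, rec in records.iterrows():
        if not rec["backbone_backbone"]:
            out["side_chain"] += 1
        elif rec["sequence_offset"] == 3:
            out["i+3->i"] += 1
        elif rec["sequence_offset"] == 4:
            out["i+4->i"] += 1
        elif rec["sequence_offset"] == 5:
            out["i+5->i"] += 1
        else:
            out["other_backbone"] += 1
    return out


def hbond_occupancy(records: pd.DataFrame, n_frames: int,
                    min_occupancy: float = 0.0) -> pd.DataFrame:
    """Per donor–acceptor pair: fraction of frames present, mean/SD distance.

    ``min_occupancy`` filters the table (the conventional report keeps pairs
    present ≥10% of the time).
    """
    cols = ["key", "occupancy", "mean_distance", "sd_distance"]
    if records.empty:
        return pd.DataFrame(columns=cols)
    grouped = records.groupby(["donor", "acceptor"])
    rows = []
    for (d, a), g in grouped:
        first = g.iloc[0]
        key = (f"{first['donor_residue']}{first['donor_name']}"
               f"->{first['acceptor_residue']}{first['acceptor_name']}")
        occ = g["frame"].nunique() / n_frames
        rows.append((key, occ, g["distance"].mean(),
                     g["distance"].std(ddof=0)))
    out = pd.DataFrame(rows, columns=cols).sort_values(
        "occupancy", ascending=False).reset_index(drop=True)
    return out[out["occupancy"] >= min_occupancy].reset_index(drop=True)


# ---------------------------------------------------------------------------
# salt bridges

def acidic_oxygens(top: Topology) -> list[int]:
    """Side-chain carboxylate O of Asp/Glu plus the C-terminal carboxylate."""
    out = []
    peptide = top.peptide_residues
    chain_last = {}
    for r in peptide:
        chain_last[r.chain_id] = r.index
    for r in peptide:
        names = _ACCEPTORS.get(r.name.upper(), ())
        for i in r.atom_indices():
            nm = top.atoms[i].name
            if r.name.upper() in ("ASP", "GLU") and nm in names:
                out.append(i)
            elif r.index == chain_last[r.chain_id] and nm in ("O", "OXT"):
                out.append(i)
    return out


def basic_nitrogens(top: Topology) -> list[int]:
    """Lys Nζ, Arg Nε/Nη, and the free N-terminal amine."""
    out = []
    peptide = top.peptide_residues
    chain_first = {}
    for r in peptide:
        chain_first.setdefault(r.chain_id, r.index)
    for r in peptide:
        for i in r.atom_indices():
            nm = top.atoms[i].name
            if r.name.upper() == "LYS" and nm == "NZ":
                out.append(i)
            elif r.name.upper() == "ARG" and nm in ("NE", "NH1", "NH2"):
                out.append(i)
            elif nm == "N" and r.index == chain_first[r.chain_id]:
                out.append(i)
    return out


def salt_bridges(traj: Trajectory, cutoff: float = 3.2) -> pd.DataFrame:
    """Salt-bridge occupancy over all acidic–basic residue pairs.

    A pair is counted in a frame when any qualifying O–N distance is below
    ``cutoff``; occupancy is the fraction of frames.  Rows carry the pair
    key (e.g. ``GLU3-ARG5``), occupancy, and the mean/SD of the per-frame
    minimum O–N distance.
    """
    top = traj.topology
    o_idx = acidic_oxygens(top)
    n_idx = basic_nitrogens(top)
    if not o_idx or not n_idx:
        import warnings
        warnings.warn("no charged residues: empty salt-bridge table")
        return pd.DataFrame(columns=["key", "occupancy", "mean_distance",
                                     "sd_distance"])
    pairs: dict[tuple[int, int], list] = {}
    for i in o_idx:
        for j in n_idx:
            ri = top.residue_of_atom(i)
            rj = top.residue_of_atom(j)
            if ri.index == rj.index and ri.chain_id == rj.chain_id:
                continue
            pairs.setdefault((ri.index, rj.index), [[], []])
            pairs[(ri.index, rj.index)][0].append(i)
            pairs[(ri.index, rj.index)][1].append(j)
    resname = {r.index: r.name for r in top.peptide_residues}
    rows = []
    for (ra, rb), (ois, njs) in sorted(pairs.items()):
        ois = sorted(set(ois))
        njs = sorted(set(njs))
        mins = np.empty(traj.n_frames)
        for k, frame in enumerate(traj.frames):
            X = frame.coordinates
            d = np.linalg.norm(X[ois][:, None, :] - X[njs][None, :, :], axis=2)
            mins[k] = d.min()
        occ = float((mins < cutoff).mean())
        rows.append((f"{resname[ra]}{ra}-{resname[rb]}{rb}", occ,
                     float(mins.mean()), float(mins.std())))
    return pd.DataFrame(rows, columns=["key", "occupancy", "mean_distance",
                                       "sd_distance"])


# ---------------------------------------------------------------------------
# ligand contacts and stacking

def ligand_contacts(
    traj: Trajectory,
    residue_index: int,
    contact_cutoff: float = 5.0,
) -> dict:
    """Proximity of one residue to the ligand, two ways.

    (a) the per-frame minimum over the residue's Cα/Cβ/Cγ to any ligand
    carbon (the monitoring series; mean ± SD reported), and (b) the
    any-heavy-atom minimum, from which the fraction of frames with a
    contact below ``contact_cutoff`` is computed.
    """
    top = traj.topology
    lig_c = [i for i, a in enumerate(top.atoms) if a.is_ligand and a.element == "C"]
    lig_all = [i for i, a in enumerate(top.atoms) if a.is_ligand]
    if not lig_all:
        raise ValueError("no ligand in topology")
    res_atoms = [i for r in top.peptide_residues if r.index == residue_index
                 for i in r.atom_indices()]
    if not res_atoms:
        raise ValueError(f"no peptide residue {residue_index}")
    mon = [i for i in res_atoms if top.atoms[i].name in ("CA", "CB", "CG",
                                                         "CG1", "CG2", "OG",
                                                         "OG1", "SG")]
    mon_series = np.empty(traj.n_frames)
    any_series = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        X = frame.coordinates
        if mon and lig_c:
            d = np.linalg.norm(X[mon][:, None, :] - X[lig_c][None, :, :], axis=2)
            mon_series[k] = d.min()
        else:
            mon_series[k] = np.nan
        d2 = np.linalg.norm(X[res_atoms][:, None, :] - X[lig_all][None, :, :],
                            axis=2)
        any_series[k] = d2.min()
    return {
        "monitor_series": mon_series,
        "monitor_mean": float(np.nanmean(mon_series)),
        "monitor_sd": float(np.nanstd(mon_series)),
        "any_atom_series": any_series,
        "contact_fraction": float((any_series < contact_cutoff).mean()),
    }


@dataclass(frozen=True)
class StackingRecord:
    frame: int
    peptide_ring: tuple
    ligand_ring: tuple
    centroid_distance: float
    interplanar_angle: float


def _resolve_rings(traj: Trajectory, rings) -> list[list[int]]:
    if isinstance(rings, str):
        if rings.lower() in ("phen", "phn", "ligand"):
            return ligand_rings_from_frame(traj.topology,
                                           traj.frames[0].coordinates)
        return ring_groups(traj.topology, rings)
    return [list(r) for r in rings]


def stacking_search(
    traj: Trajectory,
    peptide_rings,
    ligand_rings="phen",
) -> tuple[StackingRecord, pd.DataFrame]:
    """Closest ring-stacking contact over a trajectory.

    For every frame the minimum centroid distance over all peptide-ring ×
    ligand-ring combinations is recorded; returns the global-minimum frame's
    geometry and the per-frame minimum-distance table.
    """
    prings = _resolve_rings(traj, peptide_rings)
    lrings = _resolve_rings(traj, ligand_rings)
    best: StackingRecord | None = None
    per_frame = []
    for k, frame in enumerate(traj.frames):
        X = frame.coordinates
        fmin = None
        for pr in prings:
            for lr in lrings:
                dist, ang = ring_geometry(X, pr, lr)
                if fmin is None or dist < fmin[0]:
                    fmin = (dist, ang, pr, lr)
        per_frame.append((k, fmin[0], fmin[1]))
        if best is None or fmin[0] < best.centroid_distance:
            best = StackingRecord(k, tuple(fmin[2]), tuple(fmin[3]),
                                  fmin[0], fmin[1])
    table = pd.DataFrame(per_frame, columns=["frame", "min_centroid_distance",
                                             "interplanar_angle"])
    return best, table


def stacking_occupancy(
    traj: Trajectory,
    peptide_rings,
    ligand_rings="phen",
    dist_cutoff: float = 4.5,
    angle_cutoff: float = 30.0,
) -> float:
    """Fraction of frames with a face-to-face stack (distance and tilt cut)."""
    _, table = stacking_search(traj, peptide_rings, ligand_rings)
    hit = (table["min_centroid_distance"] <= dist_cutoff) & \
          (table["interplanar_angle"] <= angle_cutoff)
    return float(hit.mean())


# ---------------------------------------------------------------------------

def contact_map(traj: Trajectory) -> pd.DataFrame:
    """Mean Cα–Cα distance matrix (Å) over frames; symmetric, zero diagonal."""
    top = traj.topology
    ca = []
    ids = []
    for r in top.peptide_residues:
        i = top.find_atom(r.index, "CA")
        if i < 0:
            raise ValueError(f"residue {r.index} lacks a CA atom")
        ca.append(i)
        ids.append(r.index)
    acc = np.zeros((len(ca), len(ca)))
    for frame in traj.frames:
        X = frame.coordinates[ca]
        acc += np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    acc /= traj.n_frames
    return pd.DataFrame(acc, index=ids, columns=ids)
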