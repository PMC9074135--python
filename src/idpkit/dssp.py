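"""Kabsch–Sander secondary-structure assignment, implemented from scratch.

Backbone hydrogen bonds are scored with the electrostatic energy

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   kcal/mol

between the N–H of a donor residue and the C=O of an acceptor residue; a
bond exists when E < −0.5 kcal/mol.  Missing amide hydrogens are
reconstructed at 1.01 Å opposite the bisector of the N's two backbone
bonds.  From the bond pattern, n-turns (n = 3, 4, 5) define 3,10/α/π
helices (G/H/I; two consecutive turns minimum), bridge patterns define
parallel/antiparallel ladders (E) and isolated bridges (B), turn residues
get T, bends (Cα kink > 70°) get S, and the remainder coil (C).  When
labels collide the precedence is H > E/B > G > I > T > S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import Topology, Trajectory

__all__ = [
    "ks_hbond_energy",
    "assign_dssp",
    "ss_summary",
    "sheet_sense",
    "SSAssignment",
]

_Q = 0.084 * 332.0          # coupling constant, kcal·Å/mol
_E_CUT = -0.5               # bond threshold, kcal/mol
_NH_LEN = 1.01              # reconstructed amide N–H length, Å
_BEND_ANGLE = 70.0          # Cα(i−2)–Cα(i)–Cα(i+2) kink threshold, deg


@dataclass
class _Backbone:
    """Per-residue backbone atom indices (−1 where missing)."""
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: np.ndarray               # explicit amide H if present
    resid: np.ndarray
    is_pro: np.ndarray
    prev: np.ndarray            # index of bonded predecessor, −1 at chain start


def _backbone_table(top: Topology) -> _Backbone:
    residues = top.peptide_residues
    nres = len(residues)
    n = np.full(nres, -1, dtype=int)
    ca = np.full(nres, -1, dtype=int)
    c = np.full(nres, -1, dtype=int)
    o = np.full(nres, -1, dtype=int)
    h = np.full(nres, -1, dtype=int)
    resid = np.array([r.index for r in residues])
    is_pro = np.array([r.name.upper() == "PRO" for r in residues])
    for j, r in enumerate(residues):
        for i in r.atom_indices():
            nm = top.atoms[i].name
            if nm == "N":
                n[j] = i
            elif nm == "CA":
                ca[j] = i
            elif nm == "C":
                c[j] = i
            elif nm == "O":
                o[j] = i
            elif nm in ("H", "HN"):
                h[j] = i
    prev = np.full(nres, -1, dtype=int)
    for j in range(1, nres):
        if residues[j].chain_id == residues[j - 1].chain_id:
            prev[j] = j - 1
    return _Backbone(n, ca, c, o, h, resid, is_pro, prev)


def _amide_h(bb: _Backbone, X: np.ndarray, j: int) -> np.ndarray | None:
    """Amide H of residue j: explicit if present, else reconstructed.

    Reconstruction: 1.01 Å from N along the direction opposing the bisector
    of the N→C(prev) and N→CA bonds (sp2 nitrogen).  Chain-start and
    proline donors have no amide H.
    """
    if bb.h[j] >= 0:
        return X[bb.h[j]]
    if bb.is_pro[j] or bb.prev[j] < 0:
        return None
    p = bb.prev[j]
    if bb.c[p] < 0 or bb.n[j] < 0 or bb.ca[j] < 0:
        return None
    npos = X[bb.n[j]]
    # broken chain ⇒ treat as chain start
    if np.linalg.norm(X[bb.c[p]] - npos) > 2.5:
        return None
    u1 = X[bb.c[p]] - npos
    u1 /= np.linalg.norm(u1)
    u2 = X[bb.ca[j]] - npos
    u2 /= np.linalg.norm(u2)
    d = -(u1 + u2)
    d /= np.linalg.norm(d)
    return npos + _NH_LEN * d


def _pair_energy(X: np.ndarray, bb: _Backbone, donor: int, acceptor: int,
                 h: np.ndarray) -> float:
    npos = X[bb.n[donor]]
    cpos = X[bb.c[acceptor]]
    opos = X[bb.o[acceptor]]
    r_on = np.linalg.norm(opos - npos)
    r_ch = np.linalg.norm(cpos - h)
    r_oh = np.linalg.norm(opos - h)
    r_cn = np.linalg.norm(cpos - npos)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9
    return _Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def ks_hbond_energy(traj_or_top, coordinates=None, donor_residue: int = None,
                    acceptor_residue: int = None, frame: int = 0) -> float:
    """Kabsch–Sander N–H(donor)→C=O(acceptor) energy (kcal/mol).

    Residues are addressed by their 1-based topology index.  Raises if
    backbone atoms are missing or the donor has no amide hydrogen (chain
    start or proline).
    """
    if isinstance(traj_or_top, Trajectory):
        top = traj_or_top.topology
        X = traj_or_top.frames[frame].coordinates
    else:
        top = traj_or_top
        X = np.asarray(coordinates)
    bb = _backbone_table(top)
    jmap = {rid: j for j, rid in enumerate(bb.resid)}
    try:
        dj, aj = jmap[donor_residue], jmap[acceptor_residue]
    except KeyError as exc:
        raise ValueError(f"no residue {exc} in topology")
    for j, what in ((dj, "donor"), (aj, "acceptor")):
        need = (bb.n[j], bb.ca[j], bb.c[j]) if what == "donor" else (bb.c[j], bb.o[j])
        if any(i < 0 for i in need):
            raise ValueError(f"{what} residue {top.peptide_residues[j].index} "
                             "lacks backbone atoms")
    h = _amide_h(bb, X, dj)
    if h is None:
        raise ValueError("donor has no amide hydrogen (chain start or proline)")
    return float(_pair_energy(X, bb, dj, aj, h))


def _bond_matrix(top: Topology, X: np.ndarray) -> np.ndarray:
    """Boolean matrix don[i, j]: N–H(i) donates to C=O(j)."""
    bb = _backbone_table(top)
    nres = len(bb.resid)
    don = np.zeros((nres, nres), dtype=bool)
    ca_ok = bb.ca >= 0
    CA = np.where(ca_ok[:, None], X[np.maximum(bb.ca, 0)], np.nan)
    for i in range(nres):
        if bb.n[i] < 0 or not ca_ok[i]:
            continue
        h = _amide_h(bb, X, i)
        if h is None:
            continue
        for j in range(nres):
            if abs(i - j) <= 1:
                continue
            if bb.c[j] < 0 or bb.o[j] < 0 or not ca_ok[j]:
                continue
            # Kabsch–Sander prescreen: Cα within 9 Å
            if np.linalg.norm(CA[i] - CA[j]) > 9.0:
                continue
            if _pair_energy(X, bb, i, j, h) < _E_CUT:
                don[i, j] = True
    return don


def _ks_interchain_bond_count(top_a: Topology, Xa: np.ndarray,
                              top_b: Topology, Xb: np.ndarray) -> int:
    """Count K-S bonds between two separate chains (builder scoring hook)."""
    from .synthetic import _merge  # local import to avoid a cycle at load
    from .structure_io import Frame

    top, frame = _merge(top_a, Frame(Xa), top_b, Frame(Xb))
    don = _bond_matrix(top, frame.coordinates)
    na = len(top_a.peptide_residues)
    return int(don[:na, na:].sum() + don[na:, :na].sum())


@dataclass
class SSAssignment:
    """Per-frame, per-residue 8-state labels plus bridge bookkeeping."""
    labels: np.ndarray                  # (n_frames, n_res) of 'HGIEBTSC'
    residue_index: np.ndarray
    # per frame: list of (i, j, 'parallel'|'antiparallel') bridges (0-based)
    bridges: list

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]


def _assign_frame(top: Topology, X: np.ndarray) -> tuple[np.ndarray, list]:
    bb = _backbone_table(top)
    nres = len(bb.resid)
    labels = np.full(nres, "C", dtype="<U1")
    if nres < 5:
        return labels, []
    don = _bond_matrix(top, X)

    # n-turns: turn_n[i] ⇔ bond (i+n → i)
    turns = {n: np.zeros(nres, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(nres - n):
            if don[i + n, i]:
                turns[n][i] = True

    # bridges
    bridges: list[tuple[int, int, str]] = []
    for i in range(1, nres - 1):
        for j in range(i + 3, nres - 1):
            para = (don[j, i - 1] and don[i + 1, j]) or \
                   (don[i, j - 1] and don[j + 1, i])
            anti = (don[i, j] and don[j, i]) or \
                   (don[j + 1, i - 1] and don[i + 1, j - 1])
            if para:
                bridges.append((i, j, "parallel"))
            elif anti:
                bridges.append((i, j, "antiparallel"))

    # ladders: bridges chained along the diagonal/antidiagonal
    in_ladder = np.zeros(nres, dtype=bool)
    in_bridge = np.zeros(nres, dtype=bool)
    bset = {(i, j, t) for i, j, t in bridges}
    for i, j, t in bridges:
        if t == "parallel":
            chained = (i + 1, j + 1, t) in bset or (i - 1, j - 1, t) in bset
        else:
            chained = (i + 1, j - 1, t) in bset or (i - 1, j + 1, t) in bset
        (in_ladder if chained else in_bridge)[[i, j]] = True

    # helices: ≥2 consecutive n-turns
    helix = {n: np.zeros(nres, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(1, nres - n):
            if turns[n][i] and turns[n][i - 1]:
                helix[n][i:i + n] = True

    # turn flag: residues covered by any n-turn
    turn_flag = np.zeros(nres, dtype=bool)
    for n in (3, 4, 5):
        for i in np.flatnonzero(turns[n]):
            turn_flag[i + 1:i + n] = True

    # bend flag
    bend = np.zeros(nres, dtype=bool)
    for i in range(2, nres - 2):
        ids = (bb.ca[i - 2], bb.ca[i], bb.ca[i + 2])
        if any(k < 0 for k in ids):
            continue
        u = X[ids[1]] - X[ids[0]]
        v = X[ids[2]] - X[ids[1]]
        cosk = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.degrees(np.arccos(np.clip(cosk, -1, 1))) > _BEND_ANGLE:
            bend[i] = True

    # precedence (low → high), later assignments overwrite earlier ones
    labels[bend] = "S"
    labels[turn_flag] = "T"
    labels[helix[5]] = "I"
    labels[helix[3]] = "G"
    labels[in_bridge] = "B"
    labels[in_ladder] = "E"
    labels[helix[4]] = "H"
    return labels, bridges


def assign_dssp(traj: Trajectory) -> SSAssignment:
    """Assign 8-state secondary structure to every frame of a trajectory."""
    top = traj.topology
    residues = top.peptide_residues
    if len(residues) < 5:
        import warnings
        warnings.warn("fewer than 5 residues: all labels C")
        labels = np.full((traj.n_frames, len(residues)), "C", dtype="<U1")
        return SSAssignment(labels, np.array([r.index for r in residues]),
                            [[] for _ in range(traj.n_frames)])
    all_labels = []
    all_bridges = []
    for frame in traj.frames:
        lab, br = _assign_frame(top, frame.coordinates)
        all_labels.append(lab)
        all_bridges.append(br)
    return SSAssignment(np.array(all_labels),
                        np.array([r.index for r in residues]), all_bridges)


_GROUPS = {"helix": ("H", "G", "I"), "sheet": ("E", "B"), "other": ("T", "S", "C")}


def ss_summary(assignment: SSAssignment) -> tuple[pd.DataFrame, dict]:
    """Per-residue label percentages and grouped helix/sheet/other measures.

    Grouped values are frame×residue averages: helix = H+G+I, sheet = E+B,
    other = T+S+C; the three sum to 100.
    """
    labels = assignment.labels
    if labels.size == 0:
        raise ValueError("empty label matrix")
    states = list("HGIEBTSC")
    per_res = pd.DataFrame(
        {s: (labels == s).mean(axis=0) * 100.0 for s in states},
        index=pd.Index(assignment.residue_index, name="residue_index"),
    )
    for g, members in _GROUPS.items():
        per_res[g] = per_res[list(members)].sum(axis=1)
    grouped = {g: float((np.isin(labels, _GROUPS[g])).mean() * 100.0)
               for g in _GROUPS}
    return per_res, grouped


def sheet_sense(assignment: SSAssignment) -> pd.DataFrame:
    """Per-residue fractions of frames in parallel / antiparallel ladders."""
    nres = len(assignment.residue_index)
    para = np.zeros(nres)
    anti = np.zeros(nres)
    for k in range(assignment.n_frames):
        pk = np.zeros(nres, dtype=bool)
        ak = np.zeros(nres, dtype=bool)
        for i, j, t in assignment.bridges[k]:
            if assignment.labels[k, i] not in "EB" or \
               assignment.labels[k, j] not in "EB":
                continue
            (pk if t == "parallel" else ak)[[i, j]] = True
        para += pk
        anti += ak
    f = assignment.n_frames
    return pd.DataFrame({
        "residue_index": assignment.residue_index,
        "parallel": para / f,
        "antiparallel": anti / f,
    })
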