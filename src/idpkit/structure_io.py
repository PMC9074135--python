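"""Molecular data model, multi-model PDB reading/writing, and atom selections.

The in-memory substrate for every analysis is a :class:`Trajectory`: a
:class:`Topology` (atom metadata, residue table, peptide sequence) plus an
ordered list of :class:`Frame` coordinate sets in Å.  Files are plain
multi-model PDB; frames are delimited by MODEL/ENDMDL records and ligand
fragments (HETATM) are flagged so peptide-only analyses can exclude them.

The parser is deliberately tolerant: the element column may be absent (the
element is then inferred from the atom name), MODEL numbers need not be
sequential, and unknown HETATM atom names are mapped by element.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Topology",
    "Frame",
    "Trajectory",
    "PDBParseError",
    "PDBStructureError",
    "SelectionError",
    "ATOMIC_MASSES",
    "AA_3TO1",
    "AA_1TO3",
    "read_pdb_models",
    "write_pdb_models",
    "select",
    "ring_groups",
    "abeta_sequences",
]

# Average atomic masses (amu) for the elements that occur in peptides and in
# the Pt(phenanthroline) fragment.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "PT": 195.084,
}

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common His tautomer/protonation aliases
    "HID": "H", "HIE": "H", "HIP": "H",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items() if k not in ("HID", "HIE", "HIP")}

BACKBONE_NAMES = ("N", "CA", "C", "O")

# Side-chain ring atoms by residue type (6-membered phenol/phenyl rings and
# the 5-membered imidazole; Trp contributes both of its rings).
RING_ATOMS = {
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "HID": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "HIE": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "HIP": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
}


class PDBParseError(ValueError):
    """Raised for a malformed ATOM/HETATM line; names the offending line."""


class PDBStructureError(ValueError):
    """Raised when MODEL blocks are structurally inconsistent."""


class SelectionError(ValueError):
    """Raised for an unknown residue/atom in a selection expression."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_index: int          # 1-based
    residue_name: str
    chain_id: str
    mass: float
    is_ligand: bool = False


@dataclass(frozen=True)
class Residue:
    index: int                  # 1-based, as in Asp1 ... Ala42
    name: str
    chain_id: str
    atom_start: int             # [start, stop) into the topology atom list
    atom_stop: int
    is_ligand: bool = False

    def atom_indices(self) -> range:
        return range(self.atom_start, self.atom_stop)


@dataclass
class Topology:
    atoms: list[AtomRecord]
    residues: list[Residue]

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serial numbers must be unique")
        if any(a.mass <= 0 for a in self.atoms):
            raise ValueError("atom masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def peptide_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_ligand]

    @property
    def sequence(self) -> str:
        out = []
        for r in self.peptide_residues:
            try:
                out.append(AA_3TO1[r.name])
            except KeyError:
                raise ValueError(f"unknown peptide residue {r.name}{r.index}")
        return "".join(out)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def residue_of_atom(self, i: int) -> Residue:
        for r in self.residues:
            if r.atom_start <= i < r.atom_stop:
                return r
        raise IndexError(i)

    def find_atom(self, residue_index: int, name: str) -> int:
        """Index of a named atom inside a residue, or -1 if absent."""
        for r in self.residues:
            if r.index == residue_index:
                for i in r.atom_indices():
                    if self.atoms[i].name == name:
                        return i
        return -1


@dataclass
class Frame:
    coordinates: np.ndarray     # (n_atoms, 3) in Å
    frame_index: int = 0
    temperature: float | None = None
    time: float | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        n = self.topology.n_atoms
        for f in self.frames:
            if f.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {f.frame_index}: {f.coordinates.shape[0]} atoms, "
                    f"topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack([f.coordinates for f in self.frames])


# ---------------------------------------------------------------------------
# element inference

_NAME_RE = re.compile(r"[A-Za-z]+")


def infer_element(name: str, resname: str = "") -> str:
    """Infer an element symbol from a PDB atom name.

    Handles the two-letter metals used here (Pt) plus H/C/N/O/S/P; falls back
    to the first alphabetic character.
    """
    stripped = name.strip()
    m = _NAME_RE.search(stripped)
    if not m:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    letters = m.group(0).upper()
    if letters.startswith("PT") or resname.strip().upper() == "PT":
        return "PT"
    first = letters[0]
    if first in "HCNOSP":
        return first
    raise ValueError(f"cannot infer element from atom name {name!r}")


def _mass_of(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise ValueError(f"no mass tabulated for element {element!r}")


# ---------------------------------------------------------------------------
# PDB reading

def read_pdb_models(source: str | Path) -> Trajectory:
    """Read a (multi-model) PDB file or PDB-format text into a Trajectory.

    One Frame per MODEL block; a file without MODEL records yields a single
    frame.  HETATM atoms are flagged ``is_ligand``.  Coordinates come from
    the fixed columns 31-54 at 3-decimal precision.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)

    model_atoms: list[list[tuple]] = []
    current: list[tuple] = []
    in_model = False
    saw_model = False

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            saw_model = True
            in_model = True
            current = []
        elif rec.startswith("ENDMDL"):
            in_model = False
            model_atoms.append(current)
            current = []
        elif rec in ("ATOM  ", "HETATM") or rec.rstrip() in ("ATOM", "HETATM"):
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21:22].strip() or "A"
                resseq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}")
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = infer_element(name, resname)
            element = element.upper()
            het = rec.startswith("HETATM")
            current.append((serial, name, element, resseq, resname, chain, het, x, y, z))

    if current and not saw_model:
        model_atoms.append(current)
    elif current and in_model:      # MODEL without ENDMDL at EOF
        model_atoms.append(current)

    model_atoms = [m for m in model_atoms if m]
    if not model_atoms:
        raise PDBParseError("no ATOM/HETATM records found")

    first = model_atoms[0]
    for k, m in enumerate(model_atoms[1:], start=2):
        if len(m) != len(first):
            raise PDBStructureError(
                f"model {k} has {len(m)} atoms, model 1 has {len(first)}"
            )

    atoms: list[AtomRecord] = []
    residues: list[Residue] = []
    last_key = None
    for i, (serial, name, element, resseq, resname, chain, het, *_xyz) in enumerate(first):
        atoms.append(AtomRecord(
            serial=serial, name=name, element=element, residue_index=resseq,
            residue_name=resname, chain_id=chain, mass=_mass_of(element),
            is_ligand=het,
        ))
        key = (chain, resseq, resname)
        if key != last_key:
            residues.append(Residue(resseq, resname, chain, i, i + 1, het))
            last_key = key
        else:
            residues[-1] = replace(residues[-1], atom_stop=i + 1)

    top = Topology(atoms=atoms, residues=residues)
    frames = [
        Frame(np.array([rec[-3:] for rec in m]), frame_index=k)
        for k, m in enumerate(model_atoms)
    ]
    return Trajectory(topology=top, frames=frames)


# ---------------------------------------------------------------------------
# PDB writing

def write_pdb_models(traj: Trajectory, dest: str | Path) -> None:
    """Write a Trajectory as a standards-compliant multi-model PDB file."""
    Path(dest).write_text(pdb_text(traj))


def pdb_text(traj: Trajectory) -> str:
    lines: list[str] = []
    top = traj.topology
    multi = traj.n_frames > 1
    for k, frame in enumerate(traj.frames, start=1):
        if multi:
            lines.append(f"MODEL {k:8d}")
        for i, atom in enumerate(top.atoms):
            x, y, z = frame.coordinates[i]
            for v in (x, y, z):
                if not -999.999 <= v <= 9999.999:
                    raise ValueError(
                        f"coordinate {v:.3f} exceeds the PDB fixed-column width"
                    )
            rec = "HETATM" if atom.is_ligand else "ATOM  "
            name = atom.name
            # PDB convention: 1-letter elements start in column 14
            pname = f" {name:<3s}" if len(atom.element) == 1 and len(name) < 4 else f"{name:<4s}"
            el = atom.element.capitalize() if len(atom.element) > 1 else atom.element
            lines.append(
                f"{rec}{atom.serial:5d} {pname}{'':1s}{atom.residue_name:>3s} "
                f"{atom.chain_id:1s}{atom.residue_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{el:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# selections

def _residue_matches(res: Residue, token: str) -> bool:
    """Match tokens like TYR10, HIS, 10, 3-7 against a residue."""
    m = re.fullmatch(r"([A-Za-z]{3})?(\d+)?(?:-(\d+))?", token)
    if not m or (m.group(1) is None and m.group(2) is None):
        raise SelectionError(f"bad residue token {token!r}")
    name3, lo, hi = m.group(1), m.group(2), m.group(3)
    if name3 and res.name.upper() != name3.upper():
        return False
    if lo is not None:
        lo_i = int(lo)
        hi_i = int(hi) if hi is not None else lo_i
        if not (lo_i <= res.index <= hi_i):
            return False
    return True


def select(top: Topology, expr: str) -> list[int]:
    """Resolve a selection expression to a sorted, unique atom-index list.

    Grammar (clauses joined with ``and`` intersect):

    - ``all`` / ``protein`` / ``ligand``
    - ``backbone`` (N, CA, C, O of peptide residues), ``calpha``
    - ``name CA,CB``  (atom names, comma separated)
    - ``resid 3-5`` or ``resid 3,7,9``
    - ``resname HIS,TYR``
    - ``ring(TYR10)`` / ``ring(HIS)`` / ``ring(phen)``  (aromatic ring atoms)
    """
    clauses = [c.strip() for c in re.split(r"\s+and\s+", expr.strip()) if c.strip()]
    if not clauses:
        raise SelectionError("empty selection expression")
    result: set[int] | None = None
    for clause in clauses:
        idx = _select_clause(top, clause)
        result = idx if result is None else result & idx
    return sorted(result or set())


def _select_clause(top: Topology, clause: str) -> set[int]:
    low = clause.lower()
    if low == "all":
        return set(range(top.n_atoms))
    if low == "protein":
        return {i for i, a in enumerate(top.atoms) if not a.is_ligand}
    if low == "ligand":
        out = {i for i, a in enumerate(top.atoms) if a.is_ligand}
        if not out:
            raise SelectionError("no ligand atoms in topology")
        return out
    if low == "backbone":
        return {i for i, a in enumerate(top.atoms)
                if not a.is_ligand and a.name in BACKBONE_NAMES}
    if low in ("calpha", "ca"):
        return {i for i, a in enumerate(top.atoms)
                if not a.is_ligand and a.name == "CA"}
    if low.startswith("ring(") and clause.endswith(")"):
        groups = ring_groups(top, clause[5:-1])
        return {i for g in groups for i in g}
    if low.startswith("name "):
        names = {n.strip().upper() for n in clause[5:].split(",")}
        out = {i for i, a in enumerate(top.atoms) if a.name.upper() in names}
        if not out:
            raise SelectionError(f"no atoms named {sorted(names)}")
        return out
    if low.startswith("resid "):
        out: set[int] = set()
        for tok in clause[6:].split(","):
            matched = [r for r in top.residues if _residue_matches(r, tok.strip())]
            if not matched:
                raise SelectionError(f"no residue matches {tok.strip()!r}")
            for r in matched:
                out.update(r.atom_indices())
        return out
    if low.startswith("resname "):
        names = {n.strip().upper() for n in clause[8:].split(",")}
        out = {i for r in top.residues if r.name.upper() in names
               for i in r.atom_indices()}
        if not out:
            raise SelectionError(f"no residues named {sorted(names)}")
        return out
    raise SelectionError(f"cannot parse selection clause {clause!r}")


def ring_groups(top: Topology, token: str) -> list[list[int]]:
    """Aromatic ring atom-index groups for a residue token.

    ``ring(TYR10)`` gives the 6 phenol-ring carbons of Tyr10; ``ring(HIS)``
    every imidazole; ``ring(phen)`` enumerates the three fused six-membered
    rings of a phenanthroline HETATM residue (atom names are not assumed:
    rings are detected from the covalent geometry).
    """
    token = token.strip()
    if token.lower().startswith("ring(") and token.endswith(")"):
        token = token[5:-1].strip()
    if token.lower() in ("phen", "phn", "ligand"):
        return _ligand_rings(top)
    groups: list[list[int]] = []
    for res in top.residues:
        if res.is_ligand or not _residue_matches(res, token):
            continue
        ring_sets = RING_ATOMS.get(res.name.upper())
        if ring_sets is None:
            continue
        name_to_idx = {top.atoms[i].name: i for i in res.atom_indices()}
        for names in ring_sets:
            try:
                groups.append([name_to_idx[n] for n in names])
            except KeyError as exc:
                raise SelectionError(
                    f"residue {res.name}{res.index} lacks ring atom {exc}"
                )
    if not groups:
        raise SelectionError(f"no ring-bearing residue matches {token!r}")
    return groups


def _ligand_rings(top: Topology) -> list[list[int]]:
    """Detect six-membered rings among ligand C/N atoms by bond geometry.

    Needs coordinates; uses the *reference geometry* stored on the topology
    by the builder, or raises if none is attached.  For file-derived
    topologies call :func:`ligand_rings_from_frame` instead.
    """
    ref = getattr(top, "_ligand_reference_coords", None)
    if ref is None:
        raise SelectionError(
            "ligand ring detection needs coordinates; use ligand_rings_from_frame"
        )
    return ligand_rings_from_frame(top, ref)


def ligand_rings_from_frame(top: Topology, coordinates: np.ndarray) -> list[list[int]]:
    """Six-membered aromatic rings of the ligand, from one frame's geometry."""
    import networkx as nx

    lig = [i for i, a in enumerate(top.atoms)
           if a.is_ligand and a.element in ("C", "N")]
    if not lig:
        raise SelectionError("no ligand C/N atoms in topology")
    xyz = np.asarray(coordinates)
    g = nx.Graph()
    g.add_nodes_from(lig)
    for ii, i in enumerate(lig):
        for j in lig[ii + 1:]:
            if np.linalg.norm(xyz[i] - xyz[j]) < 1.75:
                g.add_edge(i, j)
    rings = [sorted(c) for c in nx.minimum_cycle_basis(g) if len(c) == 6]
    if not rings:
        raise SelectionError("no six-membered ligand rings found")
    return sorted(rings)


# ---------------------------------------------------------------------------

def abeta_sequences() -> dict[str, str]:
    """Canonical amyloid-β sequences: the N-terminal 16-mer and full 42-mer."""
    return {
        "abeta16": "DAEFRHDSGYEVHHQK",
        "abeta42": "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA",
    }
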