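"""Calpha-resolution protein structures, conformational ensembles and contacts.

The data model is deliberately coarse: one bead per residue at the Calpha
position (plus an optional pseudo-Cbeta), residue identities as one-letter
codes, and integer side-chain charges fixed at pH 7 (Asp/Glu -1, Lys/Arg +1,
His and everything else 0).  Internal length unit is nm throughout; PDB I/O
converts from/to Angstrom.  Residue numbering is 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "AA_CODES",
    "CHARGE",
    "ResidueRecord",
    "ProteinFrame",
    "Ensemble",
    "ContactSet",
    "ParseError",
    "read_structure",
    "write_structure",
    "apply_point_mutation",
    "compute_contacts",
    "select_snapshots",
    "pseudo_cbeta",
]

#: canonical one-letter amino-acid codes
AA_CODES = "ACDEFGHIKLMNPQRSTVWY"

#: integer side-chain charge at pH 7
CHARGE = {aa: 0 for aa in AA_CODES}
CHARGE.update({"D": -1, "E": -1, "K": 1, "R": 1})

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

#: geometric sanity bounds for validated inputs (nm)
BOND_MIN, BOND_MAX = 0.25, 0.45
CLASH_MIN = 0.2


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass(frozen=True)
class ResidueRecord:
    """One residue: 1-based index, identity, fixed pH-7 charge, coordinates (nm)."""

    index: int
    aa: str
    ca: np.ndarray
    cb: np.ndarray | None = None

    @property
    def charge(self) -> int:
        return CHARGE[self.aa]


class ProteinFrame:
    """A single conformation of a Calpha-resolution chain.

    Parameters
    ----------
    aa
        Sequence of one-letter residue codes.
    ca
        (N, 3) Calpha coordinates in nm.
    cb
        Optional (N, 3) pseudo-Cbeta coordinates; rows may be NaN where a
        residue (Gly) has none.
    time
        Optional timestamp in ns.
    """

    def __init__(self, aa: Sequence[str], ca: np.ndarray,
                 cb: np.ndarray | None = None, time: float | None = None):
        aa = list(aa)
        ca = np.asarray(ca, dtype=float)
        if ca.shape != (len(aa), 3):
            raise ValueError(f"ca shape {ca.shape} does not match {len(aa)} residues")
        for a in aa:
            if a not in CHARGE:
                raise ValueError(f"unknown residue code {a!r}")
        self.aa = aa
        self.ca = ca
        if cb is not None:
            cb = np.asarray(cb, dtype=float)
            if cb.shape != ca.shape:
                raise ValueError("cb shape must match ca shape")
        self.cb = cb
        self.time = time

    def __len__(self) -> int:
        return len(self.aa)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProteinFrame):
            return NotImplemented
        return self.aa == other.aa and np.array_equal(self.ca, other.ca)

    @property
    def charges(self) -> np.ndarray:
        return np.array([CHARGE[a] for a in self.aa], dtype=int)

    @property
    def residues(self) -> list[ResidueRecord]:
        out = []
        for i, a in enumerate(self.aa):
            cb = None
            if self.cb is not None and a != "G" and not np.any(np.isnan(self.cb[i])):
                cb = self.cb[i].copy()
            out.append(ResidueRecord(index=i + 1, aa=a, ca=self.ca[i].copy(), cb=cb))
        return out

    def copy(self) -> "ProteinFrame":
        return ProteinFrame(list(self.aa), self.ca.copy(),
                            None if self.cb is None else self.cb.copy(), self.time)

    def validate(self) -> None:
        """Check virtual-bond and clash invariants; raise ValueError on failure."""
        d = np.linalg.norm(np.diff(self.ca, axis=0), axis=1)
        bad = np.flatnonzero((d < BOND_MIN) | (d > BOND_MAX))
        if bad.size:
            raise ValueError(
                f"consecutive Calpha distance outside [{BOND_MIN}, {BOND_MAX}] nm "
                f"at residue pairs {[(int(i) + 1, int(i) + 2) for i in bad[:5]]}")
        pairs = cKDTree(self.ca).query_pairs(r=CLASH_MIN, output_type="ndarray")
        pairs = pairs[np.abs(pairs[:, 0] - pairs[:, 1]) > 1]
        if len(pairs):
            i, j = pairs[0]
            raise ValueError(f"Calpha atoms {i + 1} and {j + 1} closer than {CLASH_MIN} nm")

    def composition(self) -> dict[str, float]:
        """Amino-acid frequencies of the chain (the decoy-drawing pool)."""
        n = len(self.aa)
        return {a: self.aa.count(a) / n for a in sorted(set(self.aa))}


def pseudo_cbeta(ca: np.ndarray, aa: Sequence[str], offset: float = 0.15) -> np.ndarray:
    """Place pseudo-Cbeta atoms ``offset`` nm from each Calpha.

    The direction is the local normal of the Calpha(i-1), Calpha(i),
    Calpha(i+1) plane; chain termini reuse their neighbour's normal.
    Gly rows are NaN.
    """
    n = len(aa)
    ca = np.asarray(ca, float)
    cb = np.full((n, 3), np.nan)
    normals = np.zeros((n, 3))
    for i in range(1, n - 1):
        v1 = ca[i - 1] - ca[i]
        v2 = ca[i + 1] - ca[i]
        nrm = np.cross(v1, v2)
        mag = np.linalg.norm(nrm)
        if mag < 1e-12:  # collinear: pick any perpendicular
            ref = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(v1 / np.linalg.norm(v1), ref)) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            nrm = np.cross(v1, ref)
            mag = np.linalg.norm(nrm)
        normals[i] = nrm / mag
    if n >= 3:
        normals[0] = normals[1]
        normals[-1] = normals[-2]
    for i in range(n):
        if aa[i] != "G":
            cb[i] = ca[i] + offset * normals[i]
    return cb


class Ensemble:
    """Ordered frames over a common residue roster (an MD-trajectory stand-in)."""

    def __init__(self, frames: Iterable[ProteinFrame]):
        frames = list(frames)
        if not frames:
            raise ValueError("ensemble needs at least one frame")
        roster = frames[0].aa
        for k, f in enumerate(frames):
            if f.aa != roster:
                raise ValueError(f"frame {k} roster differs from frame 0")
        times = [f.time for f in frames]
        if all(t is not None for t in times):
            t = np.asarray(times, float)
            if np.any(np.diff(t) < 0):
                raise ValueError("timestamps must be nondecreasing")
        self.frames = frames

    @classmethod
    def from_arrays(cls, aa: Sequence[str], coords: np.ndarray,
                    times: np.ndarray | None = None) -> "Ensemble":
        coords = np.asarray(coords, float)
        if times is None:
            times = [None] * len(coords)
        return cls(ProteinFrame(list(aa), c, time=t) for c, t in zip(coords, times))

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> ProteinFrame:
        return self.frames[i]

    @property
    def roster(self) -> list[str]:
        return self.frames[0].aa

    @property
    def n_residues(self) -> int:
        return len(self.roster)

    def coords(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, N, 3), nm."""
        return np.stack([f.ca for f in self.frames])

    def times(self) -> np.ndarray:
        t = [f.time for f in self.frames]
        if any(x is None for x in t):
            raise ValueError("ensemble has no timestamps")
        return np.asarray(t, float)


@dataclass
class ContactSet:
    """Calpha-Calpha contacts of one frame: (i, j, distance) with i < j, 1-based."""

    pairs: list[tuple[int, int, float]]
    cutoff: float
    min_sep: int

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ContactSet):
            return NotImplemented
        return {(i, j) for i, j, _ in self.pairs} == {(i, j) for i, j, _ in other.pairs}

    def index_pairs(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.pairs}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["i", "j", "distance_nm"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# operations


def _scan_pdb_lines(path: Path) -> None:
    """Pre-scan ATOM/HETATM records so parse errors can name the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(f"{path}: truncated coordinate record at line {lineno}")
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError:
                    raise ParseError(f"{path}: malformed coordinates at line {lineno}") from None


def read_structure(path, format: str = "pdb") -> Ensemble:
    """Read a (multi-model) structure file into an :class:`Ensemble`.

    One frame per model; coordinates are converted Angstrom -> nm.  Residues
    without a Calpha atom are rejected, and their indices reported in a
    warning.  Formats other than PDB are delegated to mdtraj when available.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format.lower() != "pdb":
        return _read_with_mdtraj(path)
    _scan_pdb_lines(path)

    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure()  # AtomArrayStack, coords in Angstrom
    except ParseError:
        raise
    except Exception as exc:  # biotite raises various InvalidFileError subtypes
        raise ParseError(f"{path}: {exc}") from exc
    if stack.stack_depth() == 0 or stack.array_length() == 0:
        raise ParseError(f"{path}: file contains no atoms")

    amino = stack[0]
    res_ids = np.unique(amino.res_id)
    ca_mask = amino.atom_name == "CA"
    have_ca = set(amino.res_id[ca_mask].tolist())
    missing = [int(r) for r in res_ids if r not in have_ca]
    if missing:
        warnings.warn(f"{path}: residues without Calpha rejected: {missing}")
    keep_ids = [int(r) for r in res_ids if r in have_ca]
    if not keep_ids:
        raise ParseError(f"{path}: no Calpha atoms found")

    aa = []
    for rid in keep_ids:
        name = amino.res_name[(amino.res_id == rid) & ca_mask][0]
        if name not in _THREE_TO_ONE:
            raise ParseError(f"{path}: unknown residue name {name!r} at residue {rid}")
        aa.append(_THREE_TO_ONE[name])

    frames = []
    for m in range(stack.stack_depth()):
        model = stack[m]
        ca = np.empty((len(keep_ids), 3))
        cb = np.full((len(keep_ids), 3), np.nan)
        has_cb = False
        for k, rid in enumerate(keep_ids):
            sel = model.res_id == rid
            ca[k] = model.coord[sel & (model.atom_name == "CA")][0]
            cbsel = sel & (model.atom_name == "CB")
            if np.any(cbsel):
                cb[k] = model.coord[cbsel][0]
                has_cb = True
        frames.append(ProteinFrame(aa, ca * 0.1, cb * 0.1 if has_cb else None))
    return Ensemble(frames)


def _read_with_mdtraj(path: Path) -> Ensemble:
    try:
        import mdtraj
    except ImportError as exc:  # pragma: no cover
        raise ParseError("non-PDB formats require mdtraj") from exc
    traj = mdtraj.load(str(path))
    ca_idx = traj.topology.select("name CA")
    if ca_idx.size == 0:
        raise ParseError(f"{path}: no Calpha atoms found")
    aa = []
    for i in ca_idx:
        name = traj.topology.atom(int(i)).residue.name
        if name not in _THREE_TO_ONE:
            raise ParseError(f"{path}: unknown residue name {name!r}")
        aa.append(_THREE_TO_ONE[name])
    coords = traj.xyz[:, ca_idx, :]  # mdtraj is already nm
    times = traj.time / 1000.0 if traj.time is not None else None  # ps -> ns
    return Ensemble.from_arrays(aa, coords, times)


def write_structure(ensemble: Ensemble | ProteinFrame, path) -> None:
    """Write an ensemble as a multi-model PDB file (Calpha + pseudo-Cbeta)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(ensemble, ProteinFrame):
        ensemble = Ensemble([ensemble])
    aa = ensemble.roster
    n = len(aa)
    write_cb = ensemble.frames[0].cb is not None
    atoms_per_res = [(1 + (write_cb and a != "G")) for a in aa]
    n_atoms = sum(atoms_per_res)

    template = struc.AtomArray(n_atoms)
    res_id, atom_name, res_name = [], [], []
    for i, a in enumerate(aa):
        res_id.append(i + 1)
        atom_name.append("CA")
        res_name.append(_ONE_TO_THREE[a])
        if write_cb and a != "G":
            res_id.append(i + 1)
            atom_name.append("CB")
            res_name.append(_ONE_TO_THREE[a])
    template.res_id = np.array(res_id)
    template.atom_name = np.array(atom_name)
    template.res_name = np.array(res_name)
    template.chain_id = np.full(n_atoms, "A")
    template.element = np.full(n_atoms, "C")
    template.hetero = np.zeros(n_atoms, dtype=bool)

    stack = struc.AtomArrayStack(len(ensemble), n_atoms)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    for m, frame in enumerate(ensemble.frames):
        row = []
        for i in range(n):
            row.append(frame.ca[i])
            if write_cb and aa[i] != "G":
                cb = frame.cb[i] if frame.cb is not None else frame.ca[i]
                row.append(cb)
        stack.coord[m] = np.asarray(row) * 10.0  # nm -> Angstrom
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def apply_point_mutation(frame: ProteinFrame, position: int, new_aa: str) -> ProteinFrame:
    """Replace the residue identity at 1-based ``position`` with ``new_aa``.

    Coordinates are untouched; a new frame is returned.  Mutating to the
    same identity warns and returns an identical frame.
    """
    if new_aa not in CHARGE:
        raise ValueError(f"unknown residue code {new_aa!r}")
    if not 1 <= position <= len(frame):
        raise ValueError(f"position {position} outside roster 1..{len(frame)}")
    if frame.aa[position - 1] == new_aa:
        warnings.warn(f"residue {position} is already {new_aa}; identity mutation")
    out = frame.copy()
    out.aa[position - 1] = new_aa
    return out


def compute_contacts(frame: ProteinFrame, cutoff: float = 0.5, min_sep: int = 2) -> ContactSet:
    """All Calpha pairs within ``cutoff`` nm and sequence separation >= ``min_sep``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pairs = cKDTree(frame.ca).query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs):
        pairs = np.sort(pairs, axis=1)
        pairs = pairs[pairs[:, 1] - pairs[:, 0] >= min_sep]
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    d = np.linalg.norm(frame.ca[pairs[:, 0]] - frame.ca[pairs[:, 1]], axis=1) if len(pairs) else []
    out = [(int(i) + 1, int(j) + 1, float(dd)) for (i, j), dd in zip(pairs, d)]
    return ContactSet(out, cutoff=cutoff, min_sep=min_sep)


def select_snapshots(ensemble: Ensemble, window_ns: float, count: int) -> Ensemble:
    """Pick ``count`` evenly spaced frames from the trailing ``window_ns`` window.

    Order is preserved; ``count == 1`` returns the last frame of the window
    (the most relaxed conformation, by convention).
    """
    t = ensemble.times()
    t_end = t[-1]
    idx = np.flatnonzero(t >= t_end - window_ns - 1e-9)
    if idx.size == 0:
        raise ValueError("empty selection window")
    if count > idx.size:
        raise ValueError(f"requested {count} snapshots but window holds {idx.size} frames")
    if count < 1:
        raise ValueError("count must be >= 1")
    # even spacing anchored at the window end so count=1 -> last frame;
    # step = m/count >= 1 makes the floored positions strictly decreasing
    picks = np.floor(np.linspace(idx.size - 1, -1, count, endpoint=False)).astype(int)
    chosen = idx[np.sort(picks)]
    return Ensemble([ensemble.frames[int(i)] for i in chosen])
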