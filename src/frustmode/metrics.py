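"""Trajectory observables at Calpha resolution.

Superposition (Kabsch), RMSD time series and per-residue profiles, RMSF,
radius of gyration, Shrake-Rupley solvent-accessible surface area with a
uniform Calpha radius, and a virtual-bond secondary-structure assignment.
All beads carry equal mass; lengths are nm, areas nm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import Ensemble, ProteinFrame

__all__ = [
    "MetricSeries",
    "ResidueProfile",
    "superpose",
    "kabsch_fit",
    "rmsd_series",
    "per_residue_rmsd",
    "deviation_matrix",
    "rmsf",
    "radius_of_gyration",
    "sasa",
    "ss_fraction",
]

# secondary-structure thresholds on Calpha virtual-bond distances (nm);
# helix uses d(i,i+3) and d(i,i+4), strand uses d(i,i+2) with run length >= 3
HELIX_D13 = (0.49, 0.56)
HELIX_D14 = (0.58, 0.65)
STRAND_D12 = (0.64, 0.70)
STRAND_MIN_RUN = 3


@dataclass
class MetricSeries:
    """Per-frame scalar observable (units: rmsd/rg nm, sasa nm^2, ss_fraction %)."""

    name: str
    values: np.ndarray
    unit: str
    reference: int | None = None

    def mean(self) -> float:
        return float(np.mean(self.values))

    def sd(self) -> float:
        return float(np.std(self.values))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.values)), self.name: self.values})


@dataclass
class ResidueProfile:
    """Per-residue scalar profile (nm unless noted); index is 1-based."""

    name: str
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"residue_index": np.arange(1, len(self.values) + 1),
                             f"{self.name}_nm": self.values})


# ---------------------------------------------------------------------------
# superposition


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body fit of frames onto a reference.

    Parameters
    ----------
    mobile
        (F, N, 3) or (N, 3) coordinates to fit.
    reference
        (N, 3) target coordinates.

    Returns
    -------
    Fitted coordinates with the same shape as ``mobile``.  Rotations are
    proper (no reflection).
    """
    single = mobile.ndim == 2
    P = mobile[None] if single else mobile
    Q = np.asarray(reference, float)
    if P.shape[1:] != Q.shape:
        raise ValueError(f"shape mismatch: {P.shape[1:]} vs {Q.shape}")
    qc = Q.mean(axis=0)
    Qc = Q - qc
    pc = P.mean(axis=1, keepdims=True)
    Pc = P - pc
    H = np.einsum("fni,nj->fij", Pc, Qc)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("fij,fjk->fik", U, Vt))
    D = np.repeat(np.eye(3)[None], len(P), axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("fij,fjk,fkl->fil", U, D, Vt)
    fitted = np.einsum("fni,fij->fnj", Pc, R) + qc
    return fitted[0] if single else fitted


def superpose(mobile: ProteinFrame, reference: ProteinFrame,
              fit: bool = True) -> tuple[ProteinFrame, float]:
    """Superpose ``mobile`` onto ``reference``; return (fitted frame, RMSD nm).

    With ``fit=False`` the coordinates are left in place and the raw RMSD
    is returned.
    """
    if len(mobile) != len(reference):
        raise ValueError("frames have different roster lengths")
    coords = kabsch_fit(mobile.ca, reference.ca) if fit else mobile.ca.copy()
    rmsd = float(np.sqrt(np.mean(np.sum((coords - reference.ca) ** 2, axis=1))))
    out = ProteinFrame(list(mobile.aa), coords, time=mobile.time)
    return out, rmsd


# ---------------------------------------------------------------------------
# RMSD / RMSF


def deviation_matrix(ensemble: Ensemble, reference: ProteinFrame | None = None,
                     fit: bool = True) -> np.ndarray:
    """(F, N) per-frame, per-residue deviation from reference after global fit."""
    ref = (reference or ensemble.frames[0]).ca
    X = ensemble.coords()
    if X.shape[1] != ref.shape[0]:
        raise ValueError("reference roster length mismatch")
    if fit:
        X = kabsch_fit(X, ref)
    return np.linalg.norm(X - ref, axis=2)


def rmsd_series(ensemble: Ensemble, reference: ProteinFrame | None = None,
                fit: bool = True) -> MetricSeries:
    """Global RMSD vs reference (default: first frame), one value per frame."""
    dev = deviation_matrix(ensemble, reference, fit=fit)
    return MetricSeries("rmsd", np.sqrt(np.mean(dev ** 2, axis=1)), "nm", reference=0)


def per_residue_rmsd(ensemble: Ensemble, reference: ProteinFrame | None = None,
                     fit: bool = True) -> ResidueProfile:
    """Time-mean deviation of each residue from the reference after global fit."""
    dev = deviation_matrix(ensemble, reference, fit=fit)
    return ResidueProfile("rmsd_per_residue", dev.mean(axis=0))


def rmsf(ensemble: Ensemble, fit: bool = True, passes: int = 2) -> ResidueProfile:
    """Root mean square fluctuation about the (iterated) ensemble mean.

    Frames are fitted to the running mean structure; two fit-to-mean passes
    are the default, after which the profile is stationary on tested inputs.
    """
    if len(ensemble) < 2:
        raise ValueError("RMSF needs at least two frames")
    X = ensemble.coords()
    if fit:
        ref = X[0]
        for _ in range(passes):
            X = kabsch_fit(X, ref)
            ref = X.mean(axis=0)
    mean = X.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    return ResidueProfile("rmsf", fluct)


# ---------------------------------------------------------------------------
# scalar frame observables


def radius_of_gyration(frame: ProteinFrame) -> float:
    """Equal-mass radius of gyration of the Calpha trace, nm."""
    x = frame.ca - frame.ca.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(x ** 2, axis=1))))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit sphere points."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(frame: ProteinFrame, probe: float = 0.14, radius: float = 0.34,
         n_points: int = 960, per_residue: bool = False):
    """Shrake-Rupley solvent-accessible surface area, nm^2.

    Every residue is a sphere of uniform ``radius`` at its Calpha; test
    points are placed on the expanded sphere (radius + probe) and counted
    as exposed when inside no neighbouring expanded sphere.
    """
    r_ext = radius + probe
    pts = _sphere_points(n_points)
    ca = frame.ca
    tree = cKDTree(ca)
    area_sphere = 4.0 * np.pi * r_ext ** 2
    areas = np.empty(len(ca))
    neighbours = tree.query_ball_point(ca, 2 * r_ext)
    for i, xyz in enumerate(ca):
        nbr = [j for j in neighbours[i] if j != i]
        if not nbr:
            areas[i] = area_sphere
            continue
        test = xyz + r_ext * pts
        d2 = np.sum((test[:, None, :] - ca[nbr][None, :, :]) ** 2, axis=2)
        exposed = np.all(d2 > r_ext ** 2, axis=1)
        areas[i] = area_sphere * exposed.mean()
    return areas if per_residue else float(areas.sum())


def ss_assign(frame: ProteinFrame) -> np.ndarray:
    """Per-residue secondary-structure labels: 'H', 'E' or 'C'.

    Helix: a 5-residue window i..i+4 with d(i,i+3) and d(i,i+4) inside the
    ideal-helix bands marks all its residues.  Strand: a run of >= 3
    consecutive residues whose d(i,i+2) falls in the extended band marks
    residues i..i_end+2.  Helix wins on overlap.
    """
    ca = frame.ca
    n = len(ca)
    if n < 5:
        raise ValueError("secondary-structure assignment needs >= 5 residues")

    def dist(k):
        return np.linalg.norm(ca[k:] - ca[:-k], axis=1)

    d13, d14, d12 = dist(3), dist(4), dist(2)
    labels = np.full(n, "C", dtype="<U1")

    s_ok = (d12 >= STRAND_D12[0]) & (d12 <= STRAND_D12[1])
    run = 0
    for i in range(len(s_ok) + 1):
        if i < len(s_ok) and s_ok[i]:
            run += 1
        else:
            if run >= STRAND_MIN_RUN:
                labels[i - run:i + 2] = "E"
            run = 0

    h_ok = (d13[:-1] >= HELIX_D13[0]) & (d13[:-1] <= HELIX_D13[1]) \
        & (d14 >= HELIX_D14[0]) & (d14 <= HELIX_D14[1])
    for i in np.flatnonzero(h_ok):
        labels[i:i + 5] = "H"
    return labels


def ss_fraction(frame: ProteinFrame) -> float:
    """Percent of residues assigned helix or strand by Calpha geometry."""
    labels = ss_assign(frame)
    return float(100.0 * np.mean(labels != "C"))
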