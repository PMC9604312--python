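"""Essential dynamics: covariance analysis of Calpha fluctuations.

After a least-squares fit removes roto-translations, the population
covariance C = <(x - <x>)(x - <x>)^T> of the 3N Cartesian Calpha
coordinates is diagonalized; eigenvectors are the principal coordinates
(collective modes) and eigenvalues the mean-square fluctuation along them.
Projections of the trajectory on a mode give the PC series whose range
(max - min) is the PC width; reconstructing the conformations at the two
extreme projections yields a per-residue displacement profile whose large
entries flag the mobile regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import ResidueProfile, kabsch_fit
from .structure import Ensemble, ProteinFrame

__all__ = [
    "CovarianceModel",
    "ModeSet",
    "ProjectionSeries",
    "compute_covariance",
    "diagonalize",
    "variance_fraction",
    "project",
    "pc_width",
    "extreme_conformations",
    "per_residue_displacement",
    "flag_mobile_regions",
]


@dataclass
class CovarianceModel:
    """Symmetric 3N x 3N Calpha covariance (nm^2) about the fitted mean."""

    matrix: np.ndarray
    mean: np.ndarray          # (3N,), nm
    n_frames: int
    aa: list[str] = field(default_factory=list)
    reference: np.ndarray | None = None  # fit target, (N, 3)

    def __post_init__(self):
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")


@dataclass
class ModeSet:
    """Full eigen-spectrum of a covariance: descending eigenvalues (nm^2)
    and orthonormal eigenvectors (rows, 3N)."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray   # (n_modes, 3N)
    mean: np.ndarray
    aa: list[str] = field(default_factory=list)
    reference: np.ndarray | None = None


@dataclass
class ProjectionSeries:
    """Per-frame scalar projections (nm) on one principal coordinate."""

    mode: int
    values: np.ndarray

    @property
    def width(self) -> float:
        return float(self.values.max() - self.values.min())


def _fitted_flat_coords(ensemble: Ensemble, reference: ProteinFrame | None,
                        fit: bool) -> tuple[np.ndarray, np.ndarray]:
    ref = (reference or ensemble.frames[0]).ca
    X = ensemble.coords()
    if X.shape[1] != ref.shape[0]:
        raise ValueError("reference roster length mismatch")
    if fit:
        X = kabsch_fit(X, ref)
    return X.reshape(len(X), -1), ref


def compute_covariance(ensemble: Ensemble, reference: ProteinFrame | None = None,
                       fit: bool = True, fit_to_mean: bool = False) -> CovarianceModel:
    """Population (1/n) covariance of the fitted Calpha coordinates.

    Frames are fitted to ``reference`` (default: first frame); with
    ``fit_to_mean`` a second fit pass against the fitted-ensemble mean is
    applied before the covariance is formed.
    """
    if len(ensemble) < 2:
        raise ValueError("covariance needs at least two frames")
    X, ref = _fitted_flat_coords(ensemble, reference, fit)
    if fit_to_mean and fit:
        mean_frame = X.mean(axis=0).reshape(-1, 3)
        X = kabsch_fit(X.reshape(len(X), -1, 3), mean_frame).reshape(len(X), -1)
    mean = X.mean(axis=0)
    D = X - mean
    if np.allclose(D, 0.0, atol=1e-12):
        warnings.warn("all frames identical: covariance is the zero matrix")
    C = D.T @ D / len(X)
    C = 0.5 * (C + C.T)
    return CovarianceModel(matrix=C, mean=mean, n_frames=len(X),
                           aa=list(ensemble.roster), reference=ref)


def diagonalize(cov: CovarianceModel) -> ModeSet:
    """Full spectrum of the covariance, eigenvalues descending.

    The sign of each eigenvector is fixed deterministically (its
    largest-magnitude component is made positive) so downstream extreme
    conformations are reproducible run to run.
    """
    evals, evecs = np.linalg.eigh(cov.matrix)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    vectors = evecs[:, order].T.copy()
    for v in vectors:
        k = np.argmax(np.abs(v))
        if v[k] < 0:
            v *= -1
    return ModeSet(eigenvalues=evals, eigenvectors=vectors, mean=cov.mean,
                   aa=list(cov.aa), reference=cov.reference)


def variance_fraction(modes: ModeSet, n: int = 10) -> float:
    """Ratio of the sum of the first ``n`` eigenvalues to the sum of all."""
    lam = modes.eigenvalues
    if n > len(lam):
        raise ValueError("n exceeds spectrum length")
    total = lam.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum has no variance fraction")
    return float(lam[:n].sum() / total)


def project(ensemble: Ensemble, modes: ModeSet, k: int,
            fit: bool = True) -> ProjectionSeries:
    """Per-frame projection of fitted, mean-centered coordinates on mode ``k``
    (0-based)."""
    if not 0 <= k < len(modes.eigenvalues):
        raise ValueError(f"mode {k} outside spectrum")
    ref = None if modes.reference is None else ProteinFrame(
        modes.aa or ["G"] * (len(modes.mean) // 3), modes.reference)
    X, _ = _fitted_flat_coords(ensemble, ref, fit)
    vals = (X - modes.mean) @ modes.eigenvectors[k]
    return ProjectionSeries(mode=k, values=vals)


def pc_width(series: ProjectionSeries) -> float:
    """Range (max - min) of the projection series, nm."""
    return series.width


def extreme_conformations(modes: ModeSet, k: int, series: ProjectionSeries,
                          mean: np.ndarray | None = None
                          ) -> tuple[ProteinFrame, ProteinFrame]:
    """Conformations reconstructed at the min/max projection along mode ``k``.

    Extremes are mean + p_min v_k and mean + p_max v_k (reconstructed along
    the eigenvector, not the raw trajectory frames).
    """
    if series.values.size == 0:
        raise ValueError("empty projection series")
    mean = modes.mean if mean is None else np.asarray(mean, float).reshape(-1)
    v = modes.eigenvectors[k]
    p_min, p_max = float(series.values.min()), float(series.values.max())
    if modes.eigenvalues[k] <= 1e-15:
        warnings.warn(f"mode {k} has zero variance: extremes equal the mean")
        p_min = p_max = 0.0
    aa = modes.aa or ["G"] * (len(mean) // 3)
    lo = ProteinFrame(list(aa), (mean + p_min * v).reshape(-1, 3))
    hi = ProteinFrame(list(aa), (mean + p_max * v).reshape(-1, 3))
    return lo, hi


def per_residue_displacement(frame_min: ProteinFrame,
                             frame_max: ProteinFrame) -> ResidueProfile:
    """Euclidean per-residue distance between the two extreme conformations."""
    disp = np.linalg.norm(frame_max.ca - frame_min.ca, axis=1)
    return ResidueProfile("displacement", disp)


def flag_mobile_regions(profile: ResidueProfile, threshold: float = 0.6) -> set[int]:
    """1-based residue indices whose extreme-projection displacement exceeds
    ``threshold`` nm (study convention: 0.6 nm)."""
    return {int(i) + 1 for i in np.flatnonzero(profile.values > threshold)}


def spectrum_to_csv(modes: ModeSet, path, n: int | None = None) -> None:
    lam = modes.eigenvalues if n is None else modes.eigenvalues[:n]
    cum = np.cumsum(modes.eigenvalues) / modes.eigenvalues.sum()
    df = pd.DataFrame({"k": np.arange(1, len(lam) + 1),
                       "eigenvalue_nm2": lam,
                       "cumulative_fraction": cum[:len(lam)]})
    df.to_csv(path, index=False, float_format="%.8g")
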