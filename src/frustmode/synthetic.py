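"""Synthetic conformational ensembles with planted statistical structure.

This module is the stand-in for molecular dynamics: it builds Calpha-trace
folds out of ideal helix / extended-strand / random-coil segments, derives
collective directions from an elastic network model (ENM) on the fold, and
samples Gaussian ensembles whose covariance is exactly known, so that
essential-dynamics recovery can be tested against ground truth.

The ``p53_preset`` emulates the study system: a 393-residue chain with an
N-terminal disordered region, a mixed alpha/beta core and a C-terminal
region, ten planted low-frequency modes carrying a configurable fraction
(default 0.67) of the total variance, and arginines at the four hot-spot
positions 175/248/273/282 so the classic substitutions R175H, R248Q,
R273H and R282W can be applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import (AA_CODES, Ensemble, ProteinFrame, apply_point_mutation,
                        write_structure)

__all__ = [
    "FoldSpec",
    "PlantedModes",
    "build_toy_fold",
    "build_enm_modes",
    "sample_ensemble",
    "make_variant_series",
    "p53_preset",
    "P53_HOTSPOT_MUTATIONS",
    "planted_association_fixture",
    "write_ensemble_with_manifest",
]

# ideal-geometry constants (nm)
BOND = 0.38            # consecutive Calpha virtual bond
HELIX_RADIUS = 0.23    # Calpha spiral radius of an ideal alpha helix
HELIX_RISE = 0.15      # rise per residue along the helix axis
STRAND_RISE = 0.335    # rise per residue along an extended strand axis
CLASH = 0.2            # minimum allowed Calpha-Calpha distance

#: the four p53 DNA-binding hot-spot substitutions
P53_HOTSPOT_MUTATIONS = {
    "R175H": (175, "H"),
    "R248Q": (248, "Q"),
    "R273H": (273, "H"),
    "R282W": (282, "W"),
}

# average globular-protein amino-acid frequencies (Swiss-Prot scale)
DEFAULT_COMPOSITION = {
    "A": 0.083, "R": 0.055, "N": 0.040, "D": 0.054, "C": 0.014,
    "Q": 0.039, "E": 0.068, "G": 0.071, "H": 0.023, "I": 0.060,
    "L": 0.097, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.053, "W": 0.011, "Y": 0.029, "V": 0.069,
}


@dataclass(frozen=True)
class FoldSpec:
    """Recipe for a toy fold: ordered (kind, length) segments plus a seed."""

    segments: tuple[tuple[str, int], ...]
    seed: int = 0

    def __post_init__(self):
        for kind, length in self.segments:
            if kind not in {"helix", "strand", "coil"}:
                raise ValueError(f"unknown segment kind {kind!r}")
            if length <= 0:
                raise ValueError("segment lengths must be positive")
        if self.n_residues < 10:
            raise ValueError("total length must be >= 10")

    @property
    def n_residues(self) -> int:
        return sum(length for _, length in self.segments)


@dataclass
class PlantedModes:
    """Orthonormal 3N collective directions with known variances (nm^2)."""

    vectors: np.ndarray   # (n_modes, 3N), rows orthonormal
    variances: np.ndarray  # (n_modes,), strictly decreasing, > 0

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, float)
        self.variances = np.asarray(self.variances, float)
        if self.vectors.ndim != 2 or len(self.vectors) != len(self.variances):
            raise ValueError("vectors/variances shape mismatch")
        gram = self.vectors @ self.vectors.T
        if not np.allclose(gram, np.eye(len(self.vectors)), atol=1e-8):
            raise ValueError("mode vectors must be orthonormal to 1e-8")
        if np.any(self.variances <= 0) or np.any(np.diff(self.variances) > 0):
            raise ValueError("variances must be positive and nonincreasing")

    @property
    def n_modes(self) -> int:
        return len(self.variances)


# ---------------------------------------------------------------------------
# fold construction


def _helix_template(n: int) -> np.ndarray:
    theta = np.arccos(1.0 - (BOND ** 2 - HELIX_RISE ** 2) / (2.0 * HELIX_RADIUS ** 2))
    i = np.arange(n)
    return np.column_stack([HELIX_RADIUS * np.cos(i * theta),
                            HELIX_RADIUS * np.sin(i * theta),
                            HELIX_RISE * i])


def _strand_template(n: int) -> np.ndarray:
    lateral = np.sqrt(BOND ** 2 - STRAND_RISE ** 2) / 2.0
    i = np.arange(n)
    return np.column_stack([STRAND_RISE * i,
                            lateral * (-1.0) ** i,
                            np.zeros(n)])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q


def _min_dist_ok(new: np.ndarray, placed: np.ndarray, skip_last_bond: bool) -> bool:
    if placed.size == 0:
        return True
    d2 = np.sum((new[:, None, :] - placed[None, :, :]) ** 2, axis=2)
    if skip_last_bond:
        d2[0, -1] = np.inf  # bonded neighbour across the segment joint
    return bool(np.all(d2 > CLASH ** 2))


def build_toy_fold(spec: FoldSpec, composition: dict[str, float] | None = None,
                   max_retries: int = 200, max_restarts: int = 20) -> ProteinFrame:
    """Build a self-avoiding Calpha trace from the segment recipe.

    Helix segments follow the ideal alpha-helical Calpha spiral, strands an
    extended zigzag, coils a seeded self-avoiding random walk; consecutive
    Calpha distances are 0.38 nm everywhere including segment joints.
    Residue identities are drawn from ``composition`` (default: average
    protein composition).  Deterministic for a fixed seed.
    """
    comp = composition or DEFAULT_COMPOSITION
    aa_pool = sorted(comp)
    weights = np.array([comp[a] for a in aa_pool], float)
    weights = weights / weights.sum()

    for restart in range(max_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, restart]))
        coords = _attempt_build(spec, rng, max_retries)
        if coords is not None:
            aa = list(rng.choice(aa_pool, size=spec.n_residues, p=weights))
            return ProteinFrame(aa, coords)
    raise RuntimeError(
        f"self-avoidance failure: could not place fold after {max_restarts} restarts")


def _attempt_build(spec: FoldSpec, rng: np.random.Generator,
                   max_retries: int) -> np.ndarray | None:
    placed = np.empty((0, 3))
    for kind, length in spec.segments:
        if kind == "coil":
            seg = _grow_coil(length, placed, rng, max_retries)
            if seg is None:
                return None
            placed = np.vstack([placed, seg])
            continue
        template = _helix_template(length) if kind == "helix" else _strand_template(length)
        ok = False
        for _ in range(max_retries):
            rot = _random_rotation(rng)
            seg = template @ rot.T
            if placed.size:
                direction = rot @ np.array([0.0, 0.0, 1.0]) if kind == "helix" \
                    else rot @ np.array([1.0, 0.0, 0.0])
                anchor = placed[-1] + BOND * direction
                seg = seg - seg[0] + anchor
            if _min_dist_ok(seg, placed, skip_last_bond=placed.size > 0):
                ok = True
                break
        if not ok:
            return None
        placed = np.vstack([placed, seg])
    return placed


def _grow_coil(length: int, placed: np.ndarray, rng: np.random.Generator,
               max_retries: int) -> np.ndarray | None:
    seg = []
    current = placed[-1] if placed.size else np.zeros(3)
    have_prev = placed.size > 0
    for k in range(length):
        pool = np.vstack([placed, np.asarray(seg)]) if seg else placed
        for attempt in range(max_retries):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = current + BOND * u
            if _min_dist_ok(cand[None], pool, skip_last_bond=have_prev or bool(seg)):
                break
        else:
            return None
        seg.append(cand)
        current = cand
        have_prev = True
    return np.asarray(seg)


# ---------------------------------------------------------------------------
# elastic-network modes


def build_enm_modes(frame: ProteinFrame, cutoff: float = 1.2, n_modes: int = 10,
                    amplitude: float = 1.0) -> PlantedModes:
    """Low-frequency modes of a uniform-spring anisotropic network on the fold.

    Builds the 3N x 3N ENM Hessian over Calpha pairs within ``cutoff`` nm,
    removes the six near-zero rigid-body modes and returns the lowest
    ``n_modes`` with variances proportional to 1/eigenvalue, rescaled so
    the top variance equals ``amplitude`` (nm^2).
    """
    import scipy.sparse
    import scipy.sparse.csgraph
    from scipy.spatial import cKDTree

    ca = frame.ca
    n = len(ca)
    pairs = cKDTree(ca).query_pairs(r=cutoff, output_type="ndarray")
    adj = scipy.sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, _ = scipy.sparse.csgraph.connected_components(adj, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"elastic network disconnected at cutoff {cutoff} nm "
            f"({n_comp} components); increase the cutoff")
    hess = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        dv = ca[j] - ca[i]
        d2 = dv @ dv
        block = np.outer(dv, dv) / d2
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        hess[si, si] += block
        hess[sj, sj] += block
        hess[si, sj] -= block
        hess[sj, si] -= block
    evals, evecs = np.linalg.eigh(hess)
    # rigid-body (and occasional local collinear-mechanism) eigenvalues sit
    # at numerical zero (~1e-15 of the spectrum top); genuinely soft
    # internal modes reach ~1e-8 of it, so the threshold sits in between;
    # all numerically-zero modes are excluded from the planted set
    tol = max(evals[-1], 1.0) * 1e-12
    n_zero = int(np.sum(evals < tol))  # 6 for generic 3D folds, 5 for dimers
    if n_zero + n_modes > 3 * n:
        raise ValueError("too many modes requested")
    sel = slice(n_zero, n_zero + n_modes)
    vectors = evecs[:, sel].T.copy()
    variances = 1.0 / evals[sel]
    variances *= amplitude / variances[0]
    # deterministic sign: largest-magnitude component positive
    for v in vectors:
        k = np.argmax(np.abs(v))
        if v[k] < 0:
            v *= -1
    return PlantedModes(vectors=vectors, variances=variances)


# ---------------------------------------------------------------------------
# ensemble sampling


def sample_ensemble(frame: ProteinFrame, modes: PlantedModes, n_frames: int,
                    seed: int, noise_nm: float = 0.0,
                    duration_ns: float = 150.0) -> tuple[Ensemble, np.ndarray]:
    """Sample a Gaussian ensemble around ``frame`` along the planted modes.

    Each frame is mean + sum_k a_k v_k with a_k ~ Normal(0, variance_k),
    plus isotropic per-coordinate noise of sd ``noise_nm``.  Returns the
    ensemble (timestamps spread evenly over ``duration_ns``) and the exact
    analytic covariance  sum_k variance_k v_k v_k^T + noise^2 I  (3N x 3N).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    n3 = frame.ca.size
    amps = rng.normal(size=(n_frames, modes.n_modes)) * np.sqrt(modes.variances)
    disp = amps @ modes.vectors
    if noise_nm > 0:
        disp = disp + rng.normal(scale=noise_nm, size=(n_frames, n3))
    coords = frame.ca.reshape(1, -1) + disp
    times = np.linspace(0.0, duration_ns, n_frames)
    ens = Ensemble.from_arrays(frame.aa, coords.reshape(n_frames, -1, 3), times)
    true_cov = (modes.vectors.T * modes.variances) @ modes.vectors
    if noise_nm > 0:
        true_cov = true_cov + noise_nm ** 2 * np.eye(n3)
    return ens, true_cov


def make_variant_series(frame: ProteinFrame,
                        mutations: list[tuple[int, str]]) -> list[ProteinFrame]:
    """One frame per (position, new_aa) substitution, geometry untouched."""
    positions = [p for p, _ in mutations]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate mutation positions")
    return [apply_point_mutation(frame, pos, aa) for pos, aa in mutations]


# ---------------------------------------------------------------------------
# presets


def _p53_segments() -> tuple[tuple[str, int], ...]:
    """393-residue layout: disordered NTD, mixed alpha/beta core, CTD."""
    ntd = [("coil", 61), ("helix", 9), ("coil", 23)]
    core = [("coil", 8), ("strand", 6), ("coil", 7), ("strand", 5), ("coil", 9),
            ("helix", 9), ("coil", 8), ("strand", 6), ("coil", 10), ("strand", 7),
            ("coil", 9), ("strand", 5), ("coil", 9), ("helix", 10), ("coil", 9),
            ("strand", 6), ("coil", 9), ("strand", 5), ("coil", 8), ("strand", 6),
            ("coil", 9), ("helix", 12), ("coil", 7), ("strand", 6), ("coil", 9),
            ("helix", 11), ("coil", 14)]
    ctd = [("coil", 20), ("helix", 9), ("coil", 22), ("helix", 8), ("coil", 22)]
    segments = tuple(ntd + core + ctd)
    assert sum(n for _, n in segments) == 393
    return segments


def p53_preset(seed: int = 0, n_modes: int = 10, variance_fraction: float = 0.67,
               decay: float = 0.7, amplitude: float = 25.0,
               enm_cutoff: float = 1.2) -> tuple[ProteinFrame, PlantedModes, float]:
    """Build the p53-like fold and its planted mode set.

    The ten lowest ENM directions get geometrically decaying variances
    (ratio ``decay``, top value ``amplitude`` nm^2); the isotropic noise sd
    returned as third element is chosen so that the top ``n_modes``
    eigenvalues of the analytic covariance carry exactly
    ``variance_fraction`` of the total variance.  The default amplitude of
    25 nm^2 puts the PC widths (tens of nm) and the per-frame RMSD
    (~0.5 nm) of the sampled ensembles on the scale observed for the real
    393-residue protein.  Arginines are planted at the four hot-spot
    positions.
    """
    spec = FoldSpec(segments=_p53_segments(), seed=seed)
    fold = build_toy_fold(spec)
    for pos, _ in P53_HOTSPOT_MUTATIONS.values():
        fold.aa[pos - 1] = "R"
    modes = build_enm_modes(fold, cutoff=enm_cutoff, n_modes=n_modes,
                            amplitude=amplitude)
    variances = amplitude * decay ** np.arange(n_modes)
    modes = PlantedModes(vectors=modes.vectors, variances=variances)
    total = variances.sum()
    n3 = 3 * len(fold)
    f = variance_fraction
    noise_var = total * (1.0 - f) / (n3 * f - n_modes)
    return fold, modes, float(np.sqrt(noise_var))


def planted_association_fixture(seed: int = 0, n_frames: int = 2000):
    """Fixture with co-localized collective motion and destabilized contacts.

    A 120-residue fold gets a single planted mode supported on a contiguous
    'mobile' coil block whose residues are all lysine: like-charge contacts
    there are energetically frustrated, while the hydrophobic remainder is
    stable, so per-residue displacement and high-frustration density should
    rank-correlate positively.

    Returns (ensemble, mobile_block_residues, fold).
    """
    segments = (("helix", 18), ("coil", 22), ("helix", 18), ("coil", 26),
                ("helix", 18), ("coil", 18))
    spec = FoldSpec(segments=segments, seed=seed)
    fold = build_toy_fold(spec, composition={"L": 0.35, "V": 0.25, "A": 0.2,
                                             "I": 0.1, "F": 0.1})
    n = len(fold)
    block = np.arange(58, 84)  # 0-based: the central coil block
    for i in block:
        fold.aa[i] = "K"
    # one localized mode: smooth envelope on the block, common direction
    envelope = np.sin(np.pi * (np.arange(len(block)) + 0.5) / len(block)) ** 2
    vec = np.zeros((n, 3))
    vec[block, 0] = envelope
    vec = vec.reshape(-1)
    vec /= np.linalg.norm(vec)
    modes = PlantedModes(vectors=vec[None, :], variances=np.array([0.09]))
    ens, _ = sample_ensemble(fold, modes, n_frames=n_frames, seed=seed + 1,
                             noise_nm=0.01)
    return ens, block + 1, fold


def write_ensemble_with_manifest(ensemble: Ensemble, modes: PlantedModes,
                                 spec: FoldSpec, seed: int, outdir) -> None:
    """Write a generated ensemble as multi-model PDB plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_structure(ensemble, outdir / "ensemble.pdb")
    manifest = {
        "segments": [list(s) for s in spec.segments],
        "seed": seed,
        "n_frames": len(ensemble),
        "planted_variances_nm2": modes.variances.tolist(),
        "n_modes": modes.n_modes,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
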