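"""Configurational frustration of residue-residue contacts.

Each native contact energy is compared with a decoy distribution obtained
by resampling both residue identities from the chain composition and the
pair distance from the empirical native contact-distance pool.  The
frustration index is the Z-score

    F_ij = (<E_decoy> - E_native) / sd(E_decoy)

with the population sd over decoys, so positive F means the native pair is
more stabilizing than a typical alternative (minimally frustrated;
F > 0.78) and strongly negative F marks an energetically unfavourable,
highly frustrated contact (F < -1).  The pair energy combines a
statistical contact potential with Debye-screened electrostatics
(k = 4.15, i.e. a relative dielectric of 80, distances in nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .potentials import miyazawa_jernigan
from .structure import AA_CODES, CHARGE, ContactSet, Ensemble, ProteinFrame, \
    compute_contacts

__all__ = [
    "EnergyModel",
    "DecoyEnsemble",
    "FrustrationMap",
    "Cluster",
    "DegenerateDecoysError",
    "pair_energy",
    "generate_decoys",
    "frustration_index",
    "classify",
    "build_map",
    "average_map",
    "total_frustration_index",
    "find_clusters",
]

MINIMAL_THRESHOLD = 0.78   # F above this: minimally frustrated
HIGH_THRESHOLD = -1.0      # F below this: highly frustrated


class DegenerateDecoysError(ValueError):
    """Raised when the decoy energies have zero spread (F undefined)."""


@dataclass
class EnergyModel:
    """Coarse-grained pair energy: contact potential + screened electrostatics.

    Parameters
    ----------
    table
        Symmetric 20x20 residue-pair contact energies in the order of
        ``aa_order`` (dimensionless).
    k_elec
        Electrostatic constant; 4.15 corresponds to a relative dielectric
        of 80 with distances in nm and elementary charges.
    debye_nm
        Debye screening length.
    cutoff / switch_nm
        Contact well: weight 1 up to ``cutoff``, cosine-switched to 0 over
        ``switch_nm`` beyond it.
    """

    table: np.ndarray = field(default_factory=miyazawa_jernigan)
    aa_order: str = "CMFILVWYAGTSNQDEHRKP"
    k_elec: float = 4.15
    debye_nm: float = 1.0
    cutoff: float = 0.5
    switch_nm: float = 0.1

    def __post_init__(self):
        self.table = np.asarray(self.table, float)
        if self.table.shape != (20, 20) or not np.allclose(self.table, self.table.T):
            raise ValueError("contact table must be a symmetric 20x20 matrix")
        if self.k_elec <= 0:
            raise ValueError("k_elec must be positive")
        self._index = {a: i for i, a in enumerate(self.aa_order)}

    def aa_index(self, aa) -> np.ndarray:
        try:
            return np.array([self._index[a] for a in np.atleast_1d(aa)])
        except KeyError as exc:
            raise ValueError(f"unknown residue type {exc.args[0]!r}") from None

    def well_weight(self, d: np.ndarray) -> np.ndarray:
        """Distance weighting: 1 inside the well, smooth cosine to 0 beyond."""
        d = np.asarray(d, float)
        w = np.zeros_like(d)
        w[d <= self.cutoff] = 1.0
        ramp = (d > self.cutoff) & (d < self.cutoff + self.switch_nm)
        w[ramp] = 0.5 * (1.0 + np.cos(np.pi * (d[ramp] - self.cutoff) / self.switch_nm))
        return w

    def energy_arrays(self, ai: np.ndarray, aj: np.ndarray, qi: np.ndarray,
                      qj: np.ndarray, d: np.ndarray) -> np.ndarray:
        contact = self.table[ai, aj] * self.well_weight(d)
        elec = self.k_elec * qi * qj * np.exp(-d / self.debye_nm) / d
        return contact + elec


def pair_energy(model: EnergyModel, aa_i: str, aa_j: str, q_i: float, q_j: float,
                distance: float) -> float:
    """Energy of one residue pair at ``distance`` nm (symmetric in i <-> j)."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    ai = model.aa_index(aa_i)
    aj = model.aa_index(aa_j)
    return float(model.energy_arrays(ai, aj, np.array([q_i], float),
                                     np.array([q_j], float),
                                     np.array([distance], float))[0])


@dataclass
class DecoyEnsemble:
    """Decoy energy distribution for one contact (i, j), 1-based indices."""

    pair: tuple[int, int]
    native_energy: float
    decoy_energies: np.ndarray
    seed: int

    @property
    def sd(self) -> float:
        return float(np.std(self.decoy_energies))


def _composition_arrays(composition: dict[str, float]):
    if not composition:
        raise ValueError("composition must be nonempty")
    codes = sorted(composition)
    w = np.array([composition[a] for a in codes], float)
    return codes, w / w.sum()


def _distance_pool(contacts: ContactSet) -> np.ndarray:
    d = np.array([dd for _, _, dd in contacts.pairs])
    if len(np.unique(np.round(d, 12))) < 10:
        raise ValueError("distance pool too thin: need >= 10 distinct native "
                         "contact distances")
    return d


def generate_decoys(contact: tuple[int, int, float], frame: ProteinFrame,
                    composition: dict[str, float] | None = None,
                    n_decoys: int = 1000, seed: int = 0,
                    model: EnergyModel | None = None,
                    contacts: ContactSet | None = None) -> DecoyEnsemble:
    """Configurational decoys for one contact.

    Each decoy re-draws both residue identities from the chain composition
    (with replacement) and the pair distance from the empirical pool of all
    native contact distances in the frame.
    """
    if n_decoys < 1:
        raise ValueError("n_decoys must be >= 1")
    model = model or EnergyModel()
    comp = composition or frame.composition()
    codes, probs = _composition_arrays(comp)
    contacts = contacts or compute_contacts(frame, cutoff=model.cutoff)
    pool = _distance_pool(contacts)
    i, j, d_native = contact
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(codes), size=(n_decoys, 2), p=probs)
    dist = rng.choice(pool, size=n_decoys, replace=True)
    charges = np.array([CHARGE[c] for c in codes], float)
    ai = model.aa_index([codes[k] for k in pick[:, 0]])
    aj = model.aa_index([codes[k] for k in pick[:, 1]])
    energies = model.energy_arrays(ai, aj, charges[pick[:, 0]], charges[pick[:, 1]], dist)
    native = pair_energy(model, frame.aa[i - 1], frame.aa[j - 1],
                         CHARGE[frame.aa[i - 1]], CHARGE[frame.aa[j - 1]], d_native)
    return DecoyEnsemble(pair=(i, j), native_energy=native,
                         decoy_energies=energies, seed=seed)


def frustration_index(native_energy: float, decoys) -> float:
    """Z-score of the native energy against its decoy distribution.

    F = (<E_decoy> - E_native) / sd(E_decoy), population sd; positive when
    the native pair is more stabilizing (lower energy) than typical decoys.
    """
    e = decoys.decoy_energies if isinstance(decoys, DecoyEnsemble) else np.asarray(decoys, float)
    sd = float(np.std(e))
    if sd == 0.0:
        raise DegenerateDecoysError("decoy energies have zero spread; "
                                    "frustration index undefined")
    return float((e.mean() - native_energy) / sd)


def classify(F: float, minimal_gt: float = MINIMAL_THRESHOLD,
             high_lt: float = HIGH_THRESHOLD) -> str:
    """'minimal' (F > 0.78), 'high' (F < -1) or 'neutral'."""
    if F > minimal_gt:
        return "minimal"
    if F < high_lt:
        return "high"
    return "neutral"


@dataclass
class Cluster:
    """Connected group of high-frustration contacts in (i, j) map space."""

    label: str           # C1.., O1..
    members: list[tuple[int, int]]
    diagonal: bool       # True: sequence-local (C), False: tertiary (O)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class FrustrationMap:
    """Per-contact frustration scores of one structure (or snapshot average)."""

    i: np.ndarray          # 1-based residue indices, i < j
    j: np.ndarray
    distance: np.ndarray   # nm (mean over snapshots when averaged)
    F: np.ndarray
    labels: np.ndarray     # 'minimal' | 'neutral' | 'high'
    n_snapshots: int = 1
    clusters: list[Cluster] | None = None

    def __len__(self) -> int:
        return len(self.F)

    @property
    def n_high(self) -> int:
        return int(np.sum(self.labels == "high"))

    def high_pairs(self) -> list[tuple[int, int]]:
        mask = self.labels == "high"
        return list(zip(self.i[mask].tolist(), self.j[mask].tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"i": self.i, "j": self.j,
                             "distance_nm": self.distance,
                             "F": self.F, "label": self.labels})

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")

    def to_matrix(self, n_residues: int) -> np.ndarray:
        """Square residue x residue matrix of F values (NaN where no contact)."""
        m = np.full((n_residues, n_residues), np.nan)
        m[self.i - 1, self.j - 1] = self.F
        m[self.j - 1, self.i - 1] = self.F
        return m


def _score_contacts(frame: ProteinFrame, contacts: ContactSet, model: EnergyModel,
                    composition: dict[str, float], n_decoys: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Vectorized frustration scores for every contact of one frame."""
    codes, probs = _composition_arrays(composition)
    pool = _distance_pool(contacts)
    charges_by_code = np.array([CHARGE[c] for c in codes], float)

    idx_i = np.array([i - 1 for i, _, _ in contacts.pairs])
    idx_j = np.array([j - 1 for _, j, _ in contacts.pairs])
    d_nat = np.array([d for _, _, d in contacts.pairs])
    ai = model.aa_index([frame.aa[k] for k in idx_i])
    aj = model.aa_index([frame.aa[k] for k in idx_j])
    q = frame.charges.astype(float)
    e_native = model.energy_arrays(ai, aj, q[idx_i], q[idx_j], d_nat)

    n_c = len(contacts)
    pick = rng.choice(len(codes), size=(n_c, n_decoys, 2), p=probs)
    dist = rng.choice(pool, size=(n_c, n_decoys), replace=True)
    # contact term via aa-order remap of composition codes
    code_idx = model.aa_index(codes)
    da = code_idx[pick[..., 0]]
    db = code_idx[pick[..., 1]]
    e_decoy = model.table[da, db] * model.well_weight(dist) \
        + model.k_elec * charges_by_code[pick[..., 0]] * charges_by_code[pick[..., 1]] \
        * np.exp(-dist / model.debye_nm) / dist
    mean = e_decoy.mean(axis=1)
    sd = e_decoy.std(axis=1)
    if np.any(sd == 0.0):
        raise DegenerateDecoysError("zero decoy spread for at least one contact")
    return (mean - e_native) / sd


def build_map(frame: ProteinFrame, model: EnergyModel | None = None,
              n_decoys: int = 1000, seed: int = 0,
              composition: dict[str, float] | None = None,
              cutoff: float | None = None, min_sep: int = 2) -> FrustrationMap:
    """Score every contact of one frame; deterministic for a fixed seed."""
    model = model or EnergyModel()
    cutoff = model.cutoff if cutoff is None else cutoff
    contacts = compute_contacts(frame, cutoff=cutoff, min_sep=min_sep)
    if len(contacts) == 0:
        warnings.warn("frame has no contacts: empty frustration map")
        empty = np.array([], dtype=int)
        return FrustrationMap(i=empty, j=empty, distance=np.array([]),
                              F=np.array([]), labels=np.array([], dtype="<U7"))
    comp = composition or frame.composition()
    rng = np.random.default_rng(seed)
    F = _score_contacts(frame, contacts, model, comp, n_decoys, rng)
    labels = np.array([classify(f) for f in F])
    return FrustrationMap(i=np.array([i for i, _, _ in contacts.pairs]),
                          j=np.array([j for _, j, _ in contacts.pairs]),
                          distance=np.array([d for _, _, d in contacts.pairs]),
                          F=F, labels=labels)


def average_map(snapshots: Ensemble, model: EnergyModel | None = None,
                n_decoys: int = 1000, seed: int = 0,
                composition: dict[str, float] | None = None,
                cutoff: float | None = None, min_sep: int = 2,
                min_presence: float = 0.5) -> FrustrationMap:
    """Average per-contact F over snapshots, then classify the mean.

    Contacts present in fewer than ``min_presence`` of the snapshots are
    dropped.  Each snapshot gets an independent decoy stream derived from
    ``seed``.
    """
    model = model or EnergyModel()
    n_snap = len(snapshots)
    acc_F: dict[tuple[int, int], list[float]] = {}
    acc_d: dict[tuple[int, int], list[float]] = {}
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_snap)
    for frame, child in zip(snapshots.frames, children):
        m = build_map(frame, model=model, n_decoys=n_decoys,
                      seed=child, composition=composition,
                      cutoff=cutoff, min_sep=min_sep)
        for i, j, d, f in zip(m.i, m.j, m.distance, m.F):
            acc_F.setdefault((int(i), int(j)), []).append(float(f))
            acc_d.setdefault((int(i), int(j)), []).append(float(d))
    keys = sorted(k for k, v in acc_F.items() if len(v) >= min_presence * n_snap)
    if not keys:
        warnings.warn("no contact persists across snapshots: empty map")
    F = np.array([np.mean(acc_F[k]) for k in keys])
    labels = np.array([classify(f) for f in F]) if keys else np.array([], dtype="<U7")
    return FrustrationMap(i=np.array([k[0] for k in keys], dtype=int),
                          j=np.array([k[1] for k in keys], dtype=int),
                          distance=np.array([np.mean(acc_d[k]) for k in keys]),
                          F=F, labels=labels, n_snapshots=n_snap)


def total_frustration_index(fmap: FrustrationMap,
                            method: str = "high_fraction") -> float:
    """Structure-level frustration summary, percent.

    ``high_fraction`` (default): 100 x (highly frustrated contacts) /
    (total contacts).  ``scaled_mean``: 100 x mean |F| / max |F|, an
    alternative percent reading exposed for comparison.
    """
    if len(fmap) == 0:
        raise ValueError("empty frustration map")
    if method == "high_fraction":
        return float(100.0 * fmap.n_high / len(fmap))
    if method == "scaled_mean":
        absF = np.abs(fmap.F)
        return float(100.0 * absF.mean() / absF.max())
    raise ValueError(f"unknown method {method!r}")


def find_clusters(fmap: FrustrationMap, diag_band: int = 12,
                  adjacency_radius: int = 3, min_size: int = 3) -> list[Cluster]:
    """Connected components of high-frustration contacts in map space.

    Adjacency is Chebyshev distance <= ``adjacency_radius`` between (i, j)
    points; components with fewer than ``min_size`` contacts are dropped.
    A component whose median |i - j| is <= ``diag_band`` is sequence-local
    (C), otherwise tertiary (O); labels are ordered by decreasing size.
    """
    from scipy.spatial import cKDTree

    pts = np.array(fmap.high_pairs(), dtype=float)
    if len(pts) == 0:
        return []
    pairs = cKDTree(pts).query_pairs(r=adjacency_radius, p=np.inf,
                                     output_type="ndarray")
    parent = list(range(len(pts)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for k in range(len(pts)):
        groups.setdefault(find(k), []).append(k)

    comps = [g for g in groups.values() if len(g) >= min_size]
    comps.sort(key=lambda g: (-len(g), pts[g[0]][0], pts[g[0]][1]))
    clusters, n_c, n_o = [], 0, 0
    for g in comps:
        members = sorted((int(pts[k][0]), int(pts[k][1])) for k in g)
        seps = [abs(i - j) for i, j in members]
        diagonal = bool(np.median(seps) <= diag_band)
        if diagonal:
            n_c += 1
            label = f"C{n_c}"
        else:
            n_o += 1
            label = f"O{n_o}"
        clusters.append(Cluster(label=label, members=members, diagonal=diagonal))
    return clusters
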