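"""Per-variant analysis pipeline and reporting.

For each variant (wild type plus point mutants) the pipeline runs:
trajectory observables -> essential dynamics -> snapshot-averaged
frustration -> rank correlation between the per-residue displacement along
the first principal coordinate and the per-residue count of highly
frustrated contacts.  The correlation stage is this package's quantitative
formalization of the visual overlap between mobile and frustrated regions;
reports label it as such.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from . import __version__
from .ed import (compute_covariance, diagonalize, extreme_conformations,
                 flag_mobile_regions, pc_width, per_residue_displacement,
                 project, spectrum_to_csv, variance_fraction)
from .frustration import (EnergyModel, FrustrationMap, average_map,
                          find_clusters, total_frustration_index)
from .metrics import (ResidueProfile, radius_of_gyration, rmsd_series, rmsf,
                      sasa, ss_fraction)
from .structure import Ensemble, select_snapshots, write_structure
from .synthetic import (P53_HOTSPOT_MUTATIONS, make_variant_series, p53_preset,
                        sample_ensemble)

__all__ = [
    "RunConfig",
    "VariantReport",
    "PipelineError",
    "per_residue_frustration_density",
    "amplitude_frustration_correlation",
    "compare_variants",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; names the stage and variant."""

    def __init__(self, stage: str, variant: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for variant {variant!r}: {cause}")
        self.stage = stage
        self.variant = variant
        self.cause = cause


@dataclass
class RunConfig:
    """Flat, schema-validated pipeline configuration (all randomness seeded)."""

    seed: int = 0
    preset: str = "p53"
    variants: tuple[str, ...] = ("wt", "R175H", "R248Q", "R273H", "R282W")
    n_frames: int = 5000
    duration_ns: float = 150.0
    window_ns: float = 10.0
    n_snapshots: int = 100
    n_modes: int = 10
    variance_fraction_target: float = 0.67
    mode_amplitude_nm2: float = 25.0
    mode_decay: float = 0.7
    contact_cutoff_nm: float = 0.5
    min_sep: int = 2
    n_decoys: int = 1000
    displacement_threshold_nm: float = 0.6
    n_perm: int = 10000
    outdir: str = "frustmode_out"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name: f.type for f in fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "variants" in data:
            data = dict(data)
            data["variants"] = tuple(data["variants"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a flat key-value mapping")
        return cls.from_dict(data)

    def validate(self) -> None:
        if self.preset != "p53":
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.n_frames < 2 or self.n_snapshots < 1 or self.n_decoys < 1:
            raise ValueError("n_frames, n_snapshots and n_decoys must be positive")
        if not self.variants or self.variants[0] != "wt":
            raise ValueError("variants must start with the 'wt' reference")
        for v in self.variants[1:]:
            if v not in P53_HOTSPOT_MUTATIONS:
                raise ValueError(f"unknown variant {v!r}")
        if self.window_ns <= 0 or self.window_ns > self.duration_ns:
            raise ValueError("window_ns must lie within the trajectory span")


@dataclass
class VariantReport:
    """Per-variant summary: observables, collective modes, frustration,
    and the motion-frustration rank correlation."""

    variant: str
    rmsd_mean_nm: float
    rmsd_sd_nm: float
    sasa_mean_nm2: float
    sasa_sd_nm2: float
    rg_mean_nm: float
    rg_sd_nm: float
    ss_mean_pct: float
    ss_sd_pct: float
    variance_fraction_top10: float
    width_pc1_nm: float
    width_pc2_nm: float
    frustration_index_pct: float
    n_contacts: int
    n_high_contacts: int
    clusters: list[dict] = field(default_factory=list)
    mobile_residues: list[int] = field(default_factory=list)
    spearman_rho: float = float("nan")
    p_perm: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)

    def scalar_summary(self) -> dict[str, float]:
        keep = ["rmsd_mean_nm", "sasa_mean_nm2", "rg_mean_nm", "ss_mean_pct",
                "variance_fraction_top10", "width_pc1_nm", "width_pc2_nm",
                "frustration_index_pct", "spearman_rho"]
        return {k: getattr(self, k) for k in keep}


def per_residue_frustration_density(fmap: FrustrationMap,
                                    roster_length: int) -> ResidueProfile:
    """Count of highly frustrated contacts incident to each residue."""
    density = np.zeros(roster_length)
    for i, j in fmap.high_pairs():
        density[i - 1] += 1
        density[j - 1] += 1
    return ResidueProfile("frustration_density", density)


def amplitude_frustration_correlation(displacement: ResidueProfile | np.ndarray,
                                      density: ResidueProfile | np.ndarray,
                                      n_perm: int = 10000,
                                      seed: int = 0) -> tuple[float, float]:
    """Spearman rank correlation with a seeded permutation p-value.

    Ties get average ranks; p = (1 + #{|rho_perm| >= |rho|}) / (1 + n_perm)
    over ``n_perm`` shuffles of the density profile.
    """
    x = displacement.values if isinstance(displacement, ResidueProfile) else np.asarray(displacement, float)
    y = density.values if isinstance(density, ResidueProfile) else np.asarray(density, float)
    if len(x) != len(y) or len(x) < 10:
        raise ValueError("profiles must have equal length >= 10")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant profile: rank correlation undefined")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho = float(scipy.stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ry, (n_perm, 1)), axis=1)
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    num = pc @ rxc
    den = np.sqrt(np.sum(pc ** 2, axis=1) * np.sum(rxc ** 2))
    rho_perm = num / den
    p = float((1 + np.sum(np.abs(rho_perm) >= abs(rho))) / (1 + n_perm))
    return rho, p


def compare_variants(reports: dict[str, VariantReport],
                     reference: str = "wt") -> tuple[pd.DataFrame, dict]:
    """Signed deltas of every scalar summary vs the reference, plus a
    cluster inventory diff (shared when member overlap >= 50%)."""
    if reference not in reports:
        raise ValueError(f"missing reference variant {reference!r}")
    ref = reports[reference]
    ref_scalars = ref.scalar_summary()
    rows = []
    cluster_diff = {}
    ref_clusters = [set(map(tuple, c["members"])) for c in ref.clusters]
    for name, rep in reports.items():
        if name == reference:
            continue
        row = {"variant": name}
        for k, v in rep.scalar_summary().items():
            row[f"delta_{k}"] = v - ref_scalars[k]
        rows.append(row)
        var_clusters = [set(map(tuple, c["members"])) for c in rep.clusters]
        shared, gained = [], []
        matched_ref = set()
        for ci, c in enumerate(var_clusters):
            hit = None
            for ri, r in enumerate(ref_clusters):
                if len(c & r) >= 0.5 * min(len(c), len(r)):
                    hit = ri
                    break
            if hit is None:
                gained.append(rep.clusters[ci]["label"])
            else:
                shared.append(rep.clusters[ci]["label"])
                matched_ref.add(hit)
        lost = [ref.clusters[ri]["label"] for ri in range(len(ref_clusters))
                if ri not in matched_ref]
        cluster_diff[name] = {"shared": shared, "gained": gained, "lost": lost}
    df = pd.DataFrame(rows)
    return df, cluster_diff


# ---------------------------------------------------------------------------
# orchestration


def _analyze_variant(variant: str, ensemble: Ensemble, cfg: RunConfig,
                     model: EnergyModel, seed_seq: np.random.SeedSequence,
                     outdir: Path) -> VariantReport:
    vdir = outdir / variant
    vdir.mkdir(parents=True, exist_ok=True)
    decoy_seed, perm_seed = seed_seq.spawn(2)

    try:
        series = rmsd_series(ensemble)
        rg = np.array([radius_of_gyration(f) for f in ensemble.frames])
        snapshots = select_snapshots(ensemble, cfg.window_ns, cfg.n_snapshots)
        sasa_vals = np.array([sasa(f) for f in snapshots.frames])
        # secondary structure from the fitted snapshot-average structure
        # (robust to the per-frame noise bath), study convention
        from .metrics import kabsch_fit
        from .structure import ProteinFrame
        snap_coords = kabsch_fit(snapshots.coords(), snapshots.frames[0].ca)
        avg_frame = ProteinFrame(list(ensemble.roster), snap_coords.mean(axis=0))
        ss_val = ss_fraction(avg_frame)
        fluct = rmsf(ensemble)
        pd.DataFrame({"frame": np.arange(len(series.values)),
                      "rmsd_nm": series.values, "rg_nm": rg}
                     ).to_csv(vdir / "metrics.csv", index=False, float_format="%.6f")
    except Exception as exc:
        raise PipelineError("metrics", variant, exc) from exc

    try:
        cov = compute_covariance(ensemble)
        modes = diagonalize(cov)
        frac10 = variance_fraction(modes, n=min(10, len(modes.eigenvalues)))
        p1 = project(ensemble, modes, 0)
        p2 = project(ensemble, modes, 1)
        lo, hi = extreme_conformations(modes, 0, p1)
        disp = per_residue_displacement(lo, hi)
        mobile = sorted(flag_mobile_regions(disp, cfg.displacement_threshold_nm))
        spectrum_to_csv(modes, vdir / "spectrum.csv", n=30)
        pd.DataFrame({"frame": np.arange(len(p1.values)),
                      "pc1_nm": p1.values, "pc2_nm": p2.values}
                     ).to_csv(vdir / "projections.csv", index=False, float_format="%.6f")
        write_structure(Ensemble([lo, hi]), vdir / "extremes_pc1.pdb")
        _write_regions_csv(mobile, vdir / "mobile_regions.csv")
    except Exception as exc:
        raise PipelineError("essential_dynamics", variant, exc) from exc

    try:
        fmap = average_map(snapshots, model=model, n_decoys=cfg.n_decoys,
                           seed=decoy_seed, cutoff=cfg.contact_cutoff_nm,
                           min_sep=cfg.min_sep)
        fmap.clusters = find_clusters(fmap)
        frustration_pct = total_frustration_index(fmap)
        fmap.to_tsv(vdir / "frustration.tsv")
        clusters = [{"label": c.label, "type": "C" if c.diagonal else "O",
                     "members": [list(m) for m in c.members],
                     "bounding_box": [min(i for i, _ in c.members),
                                      min(j for _, j in c.members),
                                      max(i for i, _ in c.members),
                                      max(j for _, j in c.members)]}
                    for c in fmap.clusters]
        (vdir / "clusters.json").write_text(json.dumps(clusters, indent=2, sort_keys=True))
    except Exception as exc:
        raise PipelineError("frustration", variant, exc) from exc

    try:
        density = per_residue_frustration_density(fmap, ensemble.n_residues)
        rho, p = amplitude_frustration_correlation(disp, density,
                                                   n_perm=cfg.n_perm, seed=perm_seed)
    except ValueError:
        warnings.warn(f"{variant}: correlation undefined (constant profile); skipped")
        rho, p = float("nan"), float("nan")
    except Exception as exc:
        raise PipelineError("correlation", variant, exc) from exc

    profiles = pd.DataFrame({"residue_index": np.arange(1, ensemble.n_residues + 1),
                             "rmsf_nm": fluct.values,
                             "displacement_pc1_nm": disp.values,
                             "high_frustration_contacts": density.values})
    profiles.to_csv(vdir / "residue_profiles.csv", index=False, float_format="%.6f")

    return VariantReport(
        variant=variant,
        rmsd_mean_nm=series.mean(), rmsd_sd_nm=series.sd(),
        sasa_mean_nm2=float(sasa_vals.mean()), sasa_sd_nm2=float(sasa_vals.std()),
        rg_mean_nm=float(rg.mean()), rg_sd_nm=float(rg.std()),
        ss_mean_pct=float(ss_val), ss_sd_pct=0.0,
        variance_fraction_top10=frac10,
        width_pc1_nm=pc_width(p1), width_pc2_nm=pc_width(p2),
        frustration_index_pct=frustration_pct,
        n_contacts=len(fmap), n_high_contacts=fmap.n_high,
        clusters=clusters, mobile_residues=[int(r) for r in mobile],
        spearman_rho=rho, p_perm=p,
    )


def _write_regions_csv(residues: list[int], path: Path) -> None:
    """Contiguous runs of flagged residues as (start_res, end_res) rows."""
    runs = []
    for r in residues:
        if runs and r == runs[-1][1] + 1:
            runs[-1][1] = r
        else:
            runs.append([r, r])
    pd.DataFrame(runs, columns=["start_res", "end_res"]).to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> dict[str, VariantReport]:
    """Run the full per-variant pipeline; writes artifacts under
    ``config.outdir`` and returns the reports keyed by variant id."""
    cfg = config
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(cfg.seed)
    fold_seed = cfg.seed % (2 ** 31)
    fold, modes, noise = p53_preset(seed=fold_seed, n_modes=cfg.n_modes,
                                    variance_fraction=cfg.variance_fraction_target,
                                    decay=cfg.mode_decay,
                                    amplitude=cfg.mode_amplitude_nm2)
    mutations = [P53_HOTSPOT_MUTATIONS[v] for v in cfg.variants[1:]]
    variant_frames = [fold] + make_variant_series(fold, mutations)

    model = EnergyModel(cutoff=cfg.contact_cutoff_nm)
    reports: dict[str, VariantReport] = {}
    children = root.spawn(len(cfg.variants))
    for name, frame, child in zip(cfg.variants, variant_frames, children):
        sample_seed, stage_seed = child.spawn(2)
        try:
            ensemble, _ = sample_ensemble(frame, modes, n_frames=cfg.n_frames,
                                          seed=sample_seed, noise_nm=noise,
                                          duration_ns=cfg.duration_ns)
        except Exception as exc:
            raise PipelineError("simulate", name, exc) from exc
        reports[name] = _analyze_variant(name, ensemble, cfg, model,
                                         stage_seed, outdir)

    delta, cluster_diff = (None, None)
    if len(reports) > 1:
        delta, cluster_diff = compare_variants(reports)
        delta.to_csv(outdir / "variant_deltas.csv", index=False, float_format="%.6f")

    manifest = {
        "package": "frustmode",
        "version": __version__,
        "config": {**asdict(cfg), "variants": list(cfg.variants)},
        "variants": list(cfg.variants),
        "planted_variances_nm2": modes.variances.tolist(),
        "noise_nm": noise,
        "note": ("spearman_rho/p_perm quantify the overlap between PC1 "
                 "displacement and high-frustration density; this rank "
                 "statistic is this package's formalization, not a "
                 "literature-defined observable"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report_doc = {name: rep.to_dict() for name, rep in reports.items()}
    if cluster_diff is not None:
        report_doc["_cluster_diff_vs_wt"] = cluster_diff
    (outdir / "reports.json").write_text(
        json.dumps(_null_nan(report_doc), indent=2, sort_keys=True))
    return reports


def _null_nan(obj):
    """Replace NaN floats by None so report JSON stays standard-compliant."""
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {k: _null_nan(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_null_nan(v) for v in obj]
    return obj
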