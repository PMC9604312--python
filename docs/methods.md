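# Methods

`frustmode` analyzes conformational heterogeneity of a protein at Cα
resolution along two complementary axes — collective motions (essential
dynamics) and energetic degeneracy of native contacts (configurational
frustration) — and quantifies the overlap between the two. Because its
reference use case is a wild-type/point-mutant series of the p53 tumor
suppressor, it ships a synthetic conformer generator that emulates that
study design with exactly known ground truth, so every stage of the chain
can be tested quantitatively without running molecular dynamics.

## Data model

A structure is an ordered Cα trace (nm) with one-letter residue identities
and integer side-chain charges fixed at pH 7 (Asp/Glu −1, Lys/Arg +1, all
others including His 0; His is kept neutral because no titration model is
attempted at this resolution). An ensemble is an ordered list of frames
over a common roster with nondecreasing timestamps (ns); it stands in for
an MD trajectory. Validated inputs must satisfy virtual-bond sanity
(consecutive Cα distance in [0.25, 0.45] nm, no two Cα under 0.2 nm);
generated ensembles are intentionally not re-validated, since large-mode
displacements legitimately stretch virtual bonds. Pseudo-Cβ positions,
when needed, are placed 0.15 nm from the Cα along the local plane normal
of the three consecutive Cα (Gly has none). PDB I/O is multi-model, Å on
disk, nm in memory; residue numbering is 1-based with no insertion codes.

## Essential dynamics

After a proper-rotation Kabsch fit of every frame to a reference (default:
the first frame; an iterated fit-to-mean pass is available behind a flag
and changes results by less than the test tolerances on all tested
fixtures), the population (1/n) covariance of the 3N Cartesian Cα
coordinates is formed and diagonalized. Eigenvector signs are fixed
deterministically (largest-magnitude component positive) so downstream
artifacts are reproducible run to run. The reported quantities are

- the variance fraction of the top n modes, Σ_{k≤n} λ_k / Σ_k λ_k;
- per-mode projection series and their widths (max − min), reported raw
  with no per-residue normalization — collective projections over
  hundreds of residues naturally span tens of nm;
- extreme conformations, reconstructed along the eigenvector from the
  minimum/maximum observed projection (mean ± p·v_k) rather than taken
  from raw frames, so they isolate the mode of interest; the raw-frame
  reading remains available by projecting frames directly;
- the per-residue displacement between the two extremes, with residues
  above a 0.6 nm threshold flagged as mobile regions.

## Configurational frustration

Each native contact (Cα–Cα distance ≤ 0.5 nm, sequence separation ≥ 2;
both are config knobs — the underlying 5 Å "contact region" convention is
ambiguous between Cα–Cα and any-atom readings, and the Cα–Cα reading is
adopted) is scored against a decoy ensemble: each decoy re-draws both
residue identities from the chain composition (with replacement) and the
pair distance from the empirical pool of all native contact distances in
the frame. Burial/density context is not resampled; only identity and
distance are. The frustration index is the Z-score

    F_ij = (⟨E_decoy⟩ − E_native) / sd(E_decoy)

with the population sd over decoys, so F > 0 means the native pair is
more stabilizing than a typical alternative. The widely used thresholds
label contacts minimally frustrated (F > 0.78), highly frustrated
(F < −1), or neutral. Note the printed form of this index in parts of the
literature carries the opposite numerator sign and a denominator that sums
a k-independent quantity; both are inconsistent with those thresholds, and
the standard server convention above is implemented instead. Degenerate
decoy ensembles (zero spread) raise an error rather than yielding NaN.

The pair energy is a Miyazawa–Jernigan (1996) statistical contact
potential (RT units) weighted by a contact well (weight 1 inside the
cutoff, cosine-switched to 0 over 0.1 nm), plus Debye-screened
electrostatics k·q_i·q_j·exp(−d/λ_D)/d with k = 4.15, λ_D = 1 nm, and d in
nm. This coarse-grained surrogate preserves the *structure* of a real
energy function (hydrophobic pairs favourable, like-charge contacts
penalized) but not its absolute scale: frustration percentages are
therefore comparable in behaviour, not in value, to all-atom results.
With distances in nm the screened-charge term dominates the contact-table
spread at short range, which compresses Z-scores and yields fewer
highly frustrated contacts than all-atom energy functions report.

Snapshot averaging follows the study convention: 100 evenly spaced frames
from the trailing 10 ns window; per-contact F is averaged over the
snapshots in which the contact exists, contacts present in fewer than 50%
of snapshots are dropped, and the averaged F is then classified. The
structure-level summary is the percentage of highly frustrated contacts
(the "%" reading of the total index); a rescaled-mean-|F| alternative is
exposed behind a flag without any fidelity claim. Clusters of high-
frustration contacts are connected components under Chebyshev adjacency
≤ 3 in (i, j) space, discarding components under 3 contacts; a component
whose median |i − j| ≤ 12 is sequence-local (C1, C2, …), otherwise
tertiary (O1, O2, …), ordered by size.

## Motion-frustration overlap

The qualitative claim that highly frustrated regions are the ones carrying
collective motion is formalized as a Spearman rank correlation (average
ranks for ties) between (a) the per-residue displacement along the first
principal coordinate's extremes and (b) the per-residue count of highly
frustrated contacts. Significance is a seeded permutation test,
p = (1 + #{|ρ_perm| ≥ |ρ|}) / (1 + n_perm), default n_perm = 10000. This
statistic is this package's own quantitative reading of a comparison that
is usually made visually; reports label it as such. Constant profiles
(e.g., a map with no highly frustrated contact) make ρ undefined; the
pipeline records null rather than a number in that case.

## Synthetic generator

Toy folds are assembled from ideal segments: α-helical Cα spirals (radius
0.23 nm, rise 0.15 nm/residue), extended strand zigzags (rise 0.335
nm/residue), and seeded self-avoiding random-walk coils, all with exact
0.38 nm virtual bonds and 0.2 nm excluded volume; segment placement
retries random orientations and restarts boundedly before failing.
Collective directions come from an anisotropic elastic network (uniform
springs between Cα pairs within 1.2 nm); connectivity is checked on the
contact graph, and all numerically zero modes — the six rigid-body ones
plus occasional exact-zero local mechanisms at collinear termini — are
excluded before modes are selected. Ensembles are Gaussian: frame = mean +
Σ_k a_k v_k with a_k ~ N(0, σ_k²) plus isotropic per-coordinate noise, so
the analytic covariance Σ_k σ_k² v_k v_kᵀ + σ_noise² I is known exactly
and serves as the recovery oracle.

The `p53_preset` emulates the reference study design: 393 residues in an
NTD(1–93)/core(94–312)/CTD(313–393) helix/strand/coil layout, arginines
planted at hot-spot positions 175/248/273/282 so the classic R175H, R248Q,
R273H and R282W substitutions apply, identities otherwise drawn from
average globular-protein composition (the real p53 sequence is not
embedded; identity statistics, not the specific sequence, are what the
decoy scheme consumes). Ten planted modes carry geometrically decaying
variances (ratio 0.7); the noise level is set analytically as
σ²_noise = V(1 − f)/(3N·f − 10) so the top-10 eigenvalue fraction of the
analytic covariance is exactly f = 0.67. The top-mode amplitude default of
25 nm² was chosen so sampled ensembles land on the scale reported for the
real protein — PC widths of tens of nm and per-frame RMSD around 0.5–0.8
nm follow from it rather than being set directly.

What the generator does *not* emulate: temporal correlation (frames are
i.i.d., so "time" stamps only order them), anharmonicity, solvent, and
side-chain packing. Two consequences matter for interpretation. First,
the white-noise bath decorrelates contacts between snapshots, so
persistent-contact maps on the preset are sparser and less frustrated than
single-frame maps — transient like-charge contacts, which carry most high
frustration, rarely survive the 50% presence filter. Second, the
secondary-structure fraction of noisy average structures degrades relative
to the ideal fold. Passing tests therefore demonstrate correctness of the
estimators on known ground truth, not realism of the dynamics.

The planted-association fixture plants both signals in one place: a
120-residue fold whose central coil block is all-lysine (like-charge
contacts, hence highly frustrated) and carries the single planted mode
(hence large displacement), with a hydrophobic, stable remainder. The
recovered rank correlation is positive and significant (ρ ≈ 0.4–0.5,
p ≈ 10⁻⁴ at n_perm = 10000).

## Observables

RMSD/RMSF/Rg are equal-mass Cα quantities; RMSF uses two fit-to-mean
passes. SASA is Shrake–Rupley with a deterministic golden-spiral grid of
960 points per atom, uniform Cα radius 0.34 nm and probe 0.14 nm —
rotation-invariant only up to the grid discretization (~0.1%). Secondary
structure is assigned from Cα virtual-bond geometry (helix: d(i,i+3) ∈
[0.49, 0.56] nm and d(i,i+4) ∈ [0.58, 0.65] nm over 5-residue windows;
strand: d(i,i+2) ∈ [0.64, 0.70] nm in runs of ≥ 3, helix wins overlaps) —
a P-SEA-style rule set, not a DSSP reimplementation. Per-residue "RMSD vs
residue number" is implemented as the time-mean per-residue deviation
after the global fit, an interpretation the package flags as such. In the
pipeline, SASA is evaluated on the snapshot window and the
secondary-structure fraction on the fitted snapshot-average structure
(the study's convention), while RMSD/Rg are per-frame over the whole
ensemble. All-atom values from the literature are qualitative context
for these Cα observables, not equality targets.

## Numerical choices and problem sizes

Population covariance (1/n) matches the ensemble-average definition.
Batched 3×3 SVD Kabsch handles 5000-frame fits in seconds. Decoy defaults:
n_decoys = 1000 (SE on F ≈ 0.03 for well-behaved distributions; the
electrostatic heavy tail inflates this for large-|F| contacts). Default
test and report sizes — 5000 frames for spectrum recovery, 2000 frames /
50 snapshots / 500 decoys for the end-to-end report, 300–400 frames for
determinism checks — were chosen as the package's own balance between
statistical resolution and turnaround; all are config knobs.

## Known limitations

- Frustration values depend on the embedded coarse-grained energy; only
  their structure (ranking, clustering, mutant deltas) is meaningful.
- The ENM/Gaussian generator cannot test time-dependent claims (mode
  autocorrelation, convergence of sampling windows).
- Cα-only SASA and secondary structure are not comparable in absolute
  value to all-atom/DSSP numbers.
- The mutation model changes identity, charge and composition but not
  geometry; structural relaxation around a substitution is out of scope.
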