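# Methods

## The model

`neurofcd` studies the coupling between a voxel-wise molecular density map
(a PET standardized uptake value ratio, SUVR) and voxel-wise functional
centrality derived from resting-state BOLD time series.

### Functional connectivity density (FCD)

Let C_ij be the Pearson correlation between the BOLD series of voxels i and
j inside the analysis mask. Voxels are nodes of two graphs built with the
same one-sided edge rule C_ij > T_c (default T_c = 0.6; only positive
correlations count):

- **gFCD** (global FCD) of voxel i is its degree in the unrestricted graph:
  the number of mask voxels anywhere with C_ij > T_c.
- **lFCD** (local FCD) restricts edges to the spatially contiguous cluster
  grown from the seed: starting from {i}, a voxel joins when it correlates
  with the seed above T_c *and* touches the current cluster under the voxel
  neighborhood (6/18/26-connected, default 26); growth stops when no
  adjacent supra-threshold voxel remains. The count is the cluster size
  minus one. Equivalently, lFCD is the size (minus one) of the connected
  component containing the seed of the seed's supra-threshold voxel set.
- **long-range FCD** = gFCD − lFCD, the seed's connections to spatially
  disjoint clusters (interregional centrality). It is nonnegative by
  construction because every cluster member is, by the growth rule,
  supra-threshold with respect to the seed.

Counts are natural-log transformed — srFCD = log lFCD, lrFCD =
log (gFCD − lFCD) — to tame their heavy right tails. The log base only
rescales the maps and cannot change any downstream statistic, because all
inference is rank-based. Voxels with a zero count have no defined log and
become *missing* by default (`zero_handling="mask_missing"`); a `log1p`
variant exists as a sensitivity option. Missing values are propagated
(never zero-filled) through smoothing, ROI means and correlations.

Smoothing of srFCD/lrFCD uses a missing-aware Gaussian kernel: weights are
renormalized over present voxels, so constants are preserved and missing
voxels neither receive nor contribute mass. Volumetric (non-masked)
smoothing, used for SUVR and tissue probabilities, is a plain separable
Gaussian with zero-padded boundaries; quantitative checks are therefore
stated on interior voxels.

Design choices where the construction was genuinely open:

- cluster membership requires correlation with the *seed*, not with any
  cluster member (the literal cluster-growing rule);
- the threshold is one-sided (anticorrelations never create edges);
- the default neighborhood is 26-connected, configurable, since volumetric
  implementations differ;
- the count convention is "edges" (cluster size − 1); `cluster_size` is
  available for cross-tool comparison.

### SUVR

The PET summed-uptake volume is divided by the mean uptake in a
white-matter reference region, defined voxel-wise by WM probability > 0.9
with 8 mm-smoothed GM < 0.05 and CSF < 0.05 (all strict inequalities;
boundary voxels are measure-zero on continuous data). The SUVR map is then
smoothed, restricted to the gray-matter mask (GM probability > 0.10) and to
SUVR > 1 — in that order; smoothing before restriction changes edge voxels,
so the order is fixed in `StudyConfig` and the CLI. The 30–50 min frame
summation is treated as upstream: the module consumes one already-summed
volume per participant.

### Group inference

Two levels:

1. **Whole-map**: ROI means of the group-mean SUVR and FCD maps are
   correlated across ROIs with Spearman's rank test (missing-aware ROI
   means: arithmetic mean over present voxels).
2. **Within-ROI/network**: per participant, the voxel-wise Spearman
   correlation between that participant's SUVR and FCD maps inside the
   region; the per-participant coefficients are Fisher z-transformed
   (z = atanh ρ, clipped at atanh(1 − 1e-7) when |ρ| = 1) and the group
   p-value is a two-sided one-sample t-test of the z values against zero.
   The t-on-z pooling rule is a design decision: it is the standard
   variance-stabilized treatment of pooled correlations and the natural
   reading of "Fisher transform, then test".

Multiple comparisons across ROIs plus networks are corrected in two steps:
a strict Bonferroni step (p < α/m with m fixed by the study design, the
number of ROIs plus networks — not by the data), then a spin-based spatial
permutation step applied only to Bonferroni survivors. Normality
diagnostics (Lilliefors-corrected Kolmogorov–Smirnov, Shapiro–Wilk) are
computed for reporting only; inference is always rank-based.

The **second-level** analysis asks whether regions of higher FCD also
couple more strongly with SUVR: Spearman correlation, across ROIs surviving
both correction steps (regions the spin cannot cover are retained, as in
the two-step reporting convention), between ROI mean FCD and ROI mean z.

### Spin permutation

Spatially autocorrelated maps make exchangeability-based permutation tests
anti-conservative (the test suite demonstrates this with a naive vertex
shuffle, which rejects ~28% of smooth independent nulls at the 5% level).
The spin test instead rotates one map over the sphere, preserving its
spatial covariance:

- meshes are order-k icospheres (10·4^k + 2 vertices; order 5 gives 10,242
  per hemisphere, 20,484 bilaterally), one per hemisphere;
- volumetric maps are read at each vertex from the 1 mm-resampled volume:
  trilinear interpolation evaluated at the center of the 1 mm voxel
  containing the vertex coordinate. Interpolation is missing-aware
  (weights renormalized over present corners; a vertex is missing only when
  every surrounding voxel is missing) — with strictly NaN-propagating
  interpolation, structures only a few voxels across would lose all
  vertices;
- rotations are composed from Euler angles drawn independently and
  uniformly on [0, 2π) about x, y and z. This per-axis recipe is *not* the
  Haar measure on SO(3); it is kept as the default deliberately, with a
  `haar=True` option for sensitivity analysis;
- each vertex receives the value of the original vertex nearest its rotated
  position; the left hemisphere uses the sagittally mirrored rotation
  M·R·M (configurable off). Spinning an already-spun map composes the
  rotations and resamples once from the source values: naive re-resampling
  compounds nearest-vertex quantization, a scale-free ~9% mismatch per
  round trip at any mesh order, whereas single-resampling composition makes
  a rotation followed by its inverse recover the map exactly;
- p = #(null ≥ observed)/n_perm, one-sided, ties counting against the
  hypothesis; only the SUVR map is spun. Null draws undefined on the
  restriction also count against the hypothesis (conservative). An
  add-one option ((k+1)/(n+1)) exists but is off by default. Within-ROI
  spin tests restrict the statistic to the ROI's vertices while the
  rotation stays global; non-spinnable regions (subcortex/cerebellum
  analogues, or ROIs too sparse on the mesh) are reported "not covered"
  and skipped.
- the correlation statistic inside the spin test defaults to Spearman for
  consistency with the rest of the analysis; Pearson is available.

Calibration: over 200 independent smooth-field null pairs at n_perm = 200,
the spin p-values pass a Kolmogorov uniformity check at the 5% level (the
test suite recomputes this).

## The synthetic study

Real PET/fMRI data of this kind is access-restricted, so the package ships
a seeded generator that emulates the features the pipeline depends on, with
planted ground truth.

**Head geometry.** An isotropic grid (default 24³ voxels at 2 mm) holds a
spherical white-matter core, a gray-matter shell and CSF outside, with
smooth radial probability profiles. The WM reference-mask criteria select a
nonempty region strictly inside the core.

**BOLD.** Every voxel series is bandpass-shaped white noise (0.01–0.08 Hz
at TR = 2.5 s, matching the pipeline's optional bandpass, which is thus a
near no-op on synthetic data), standardized to zero mean and unit variance.
Hubs are voxel balls in the GM shell sharing latent series with loadings
(√ρ_b, √(ρ_w − ρ_b), √(1 − ρ_w)) for the pair latent, hub latent and
private noise, so within-hub correlation is exactly ρ_w and cross-hub
correlation within a long-range pair exactly ρ_b (requiring ρ_w ≥ ρ_b:
local structure dominates locally). Ground truth exposes each voxel's
planted local degree (hub size − 1) and long-range degree (partner hub
size).

**Default layout.** Ten azimuthal-sector ROIs, each with a small and a
large hub on staggered rings; antipodal sectors carry size-matched hubs
joined by long-range pairs (ρ_w = 0.9, ρ_b = 0.7 by default). The
size ladder grades the sectors so ROI-mean SUVR, srFCD and lrFCD share a
planted ranking (driving the whole-map association), while the two hub
sizes inside each ROI create within-ROI degree contrast (driving the
within-ROI association). The layout needs ≥ 20 voxels per axis; grids of
22+ use a larger hub-size ladder.

**SUVR.** The PET-like volume is baseline + β · (normalized planted total
degree) + Gaussian noise (σ default 0.1) in GM, shifted so the GM minimum
exceeds 1 after reference scaling; the WM core sits at 1 so the reference
division is a near-identity. β (default 0.8) is the planted coupling; a
per-voxel β map can plant coupling gradients. Each participant draws its
own noise around the shared planted signal.

**Scale matching.** The synthetic head spans ~48 mm, about a third of a
real head, and its hubs are a few voxels across. The desk-scale
`StudyConfig` therefore defaults to 4 mm FWHM smoothing for both SUVR and
log-FCD maps; an 8 mm kernel on this geometry is wider than the planted
structures and averages away the within-ROI contrast the analysis is meant
to detect. The individual operations keep 8 mm defaults, the convention for
full-size data.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: hemodynamic response shapes, head motion and
scanner noise spectra, spatially varying tissue contrast, partial-volume
effects, anatomically realistic parcellations, and hubs with graded
(non-flat) internal degree profiles. Recovery results demonstrate that the
algorithms detect what was planted, not that real acquisitions carry such
signals.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run desk-scale configurations
chosen as this package's own validation conditions: 20³-voxel studies with
10 participants and 120 timepoints for recovery replicates (100 replicates
in the suite), 6×6×6×60 volumes for exact oracle comparisons (50 seeded
volumes, all three neighborhoods), 400 null families of 90 tests for
family-wise error, and order-2 bilateral meshes with n_perm = 200 for spin
calibration (order 5 for the mesh-size and machinery checks). The pipeline
reaches paper-scale settings (35 participants, n_perm = 1000, 8 mm kernels,
full-size grids) by configuration.

## Numerical choices

- Bulk correlations are computed as float32 matrix products for speed, and
  every product within 1e-4 of the threshold is re-evaluated in float64, so
  threshold decisions are exact (tests require integer equality with
  float64 oracles); the single-pair `pairwise_correlation` is pure float64.
- Zero-variance series inside the analysis mask are reported via a warning
  and counted as connected to nothing.
- The bandpass is a frequency-domain mask with a cosine roll-off over one
  bin and exact DC removal; the contract is stated in attenuation terms, so
  any compliant filter would pass the same tests.
- Grids are axis-aligned only (diagonal affine + offset); compatibility is
  equality of shape, voxel size and offset within 1e-6 mm. Oblique
  orientations are rejected at read time.
- Spearman p-values use the large-sample t approximation (region voxel
  counts are large); ties get average ranks.
- All randomness flows from `numpy.random.default_rng` seeded by
  (study seed, stream tag, index); every reported quantity is reproducible
  bit-for-bit from the seed on one platform.

## Known limitations

- lFCD's literal seed-correlation growth rule means the cluster is not a
  connected component of the full thresholded graph; alternative readings
  (correlation with any cluster member) would give larger clusters.
- The Euler-angle spin null is slightly non-uniform over SO(3); calibration
  tests show this does not measurably distort p-values at desk scale.
- The per-ROI group p-value entering Bonferroni is a t-test on Fisher z;
  other pooling rules (e.g. Wilcoxon on z) would change borderline ROIs.
- The pipeline assumes inputs share a common grid; no registration or
  resampling between arbitrary grids is provided (only the internal 1 mm
  read-out used by the spin projection).
- Weighted (unthresholded) degree, negative-correlation networks and any
  directionality are out of scope.
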