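# Methods

This note documents the models, parameter defaults and numerical choices in
`perilad`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Nucleus imaging

A nucleus is a 3D voxel grid with a DAPI channel and up to two FISH/painting
channels; the voxel size (z, y, x, in μm) is metadata carried with every
image and all geometry is computed in physical units. Segmentation is
deterministic: Otsu threshold on DAPI, largest 3D connected component,
per-slice hole filling. (Interactive boundary tracing, as used in practice
with ImageJ, is not reproducible; an automatic rule is required for
testability.)

**Distance to the nuclear periphery.** The boundary distance field is the
anisotropy-aware Euclidean distance transform of the mask: the distance from
each inside voxel centre to the nearest outside voxel centre. For a flat,
axis-aligned boundary this overshoots the geometric surface by exactly half
a voxel, but for the curved, voxelized boundary of a segmented nucleus the
outside voxel centres intrude past the underlying smooth surface and the
transform is close to unbiased: on digital spheres of radius 2.5 μm the mean
offset against the analytic distance is ~0.25 voxel, and the shell-volume
statistics below land within their tolerances without correction. A
half-voxel-subtracting `edge="surface"` mode is available for locally flat
boundaries. Spot distances interpolate the field trilinearly at the
intensity-weighted spot barycenter — the distance is measured from the
barycenter, not the spot edge — and a barycenter that lands outside the mask
is reported as distance 0 with a flag rather than a negative distance.

**Two-sample comparison.** Probe classes are compared with a two-sided
Mann-Whitney U test (normal approximation with tie correction; group sizes
in this setting are ~40–70 spots). Two-sided is the conservative choice
when the direction is not fixed a priori. Significance codes: `**` p < 0.01,
`*` 0.01 ≤ p < 0.05, `ns` otherwise; summaries are formatted "mean ± sd, n".
Note the package measures true 3D distances; measurements done on a single
focal plane (2D) are a special case obtained by passing single-slice images.

**Morphology.** Volume is voxel count × voxel volume. Surface area comes
from a marching-cubes mesh of the Gaussian-smoothed mask (σ = 1 voxel):
meshing the hard 0/1 volume produces a staircase surface whose area is
biased ~9% high, which the smoothing removes (residual error < 0.3%, so the
Wadell sphericity π^(1/3)(6V)^(2/3)/A is capped at 1). Sphericity is not
uniquely defined in the imaging literature; the Wadell measure is the
standard choice and is testable against analytic shapes.

## Painting profiles and P0.5

The per-nucleus cumulative profile is the fraction of a channel's in-mask
signal at boundary distance ≤ d, evaluated on a 0-to-max grid in 0.05 μm
steps with linear interpolation for the P₀.₅ read-out at 0.5 μm. Signal is
weighted by raw intensity by default (`binary=True` weights every
signal-carrying voxel equally). Because nuclei flatten where they contact
the slide, the two lowest z-slices of the mask's bounding box are excluded
by default (`exclude_bottom_slices=2`); signal placement along z is
independent of boundary distance, so the exclusion does not bias the
retained profile. Paired green/red P₀.₅ values are compared with a
two-sided Wilcoxon signed-rank test, dropping zero differences (Wilcoxon's
original rule — ties are likely on coarse grids); the count of nuclei with
green > red is reported alongside.

## Hi-C compartments

**Balancing.** Iterative correction equalizes matrix marginals: bins in the
lowest 2% of coverage (and all empty bins) are masked, then the matrix is
repeatedly divided by its mean-1-normalized marginals until the maximum
relative marginal deviation falls below eps = 1e-4 (configurable). The
marginal update is damped by a square root: the undamped symmetric update
enters a period-2 oscillation on near-disconnected maps (a strong
checkerboard with s → 1 splits the contact graph into two components).
Convergence is reported honestly (`converged`, `final_eps`); balancing a
balanced matrix is a no-op.

**O/E and correlation.** Expected contact at separation d is the mean of
retained entries on that diagonal, so each diagonal of O/E averages exactly
1 — O/E is already "relative to the average" at its distance. Compartments
are the sign of the leading eigenvector of the Pearson correlation matrix
between O/E rows (pairwise NaN deletion), oriented so the eigenvector
correlates positively with a user-supplied track (ground-truth labels in
simulations; gene density or an active mark on real data — the orientation
of a Hi-C eigenvector is arbitrary without such an anchor). One subtlety:
forcing uniform coverage onto a finite chromosome whose expectation is pure
distance decay leaves a smooth positional factor in O/E (edge bins
inflated) that per-diagonal normalization cannot remove and that correlates
all rows positively (+0.23 mean on null maps). `correlation_matrix`
therefore removes residual multiplicative row factors from the O/E matrix
(a few damped marginal sweeps; the true O/E has flat marginals) before
computing correlations; the raw behaviour is available with
`relevel=False`.

**Strength.** Compartment strength collects O/E over all unmasked pairs
within 1 Mb separation (configurable), split into cross-compartment (A–B)
and within-compartment sets; the headline statistic is the mean A–B O/E and
two genotypes are compared by two-sided Mann-Whitney on their A–B sets.
Cross-genotype contrasts use one shared compartment annotation (in
simulations the generator's labels; on real data the wild-type call):
labels called from a structureless map select on noise and bias the A–B
mean upward. Trans-contact fractions are simple count ratios per
chromosome pair and sum to 1 with the cis fractions.

## NP-interaction regression

The LASSO follows the defaults of the standard R implementation: features
standardized internally (per training fold during CV; learned on the
training chromosomes only in the held-out comparison), a 100-point
log-spaced λ grid from λ_max = max|Xᵀy|/n down to 1e-4·λ_max, tenfold
cross-validation with seeded random fold assignment (contiguous-block folds
are available to respect genomic autocorrelation), and the one-standard-
error rule: λ.1se is the largest λ whose CV MSE is within one standard
error of the minimum. Coefficients are reported on the original feature
scale; the fitted solution satisfies the KKT subgradient conditions to
< 1e-6 (checked in the tests, and against the R implementation directly).
The distance-to-PR feature is measured from the window midpoint to the
nearest PR boundary (0 for windows overlapping a PR); the anchor point is a
convention, immaterial at 20-kb windows against Mb-scale distances. Model
comparison trains both feature sets on chromosomes 1–3 and scores MSE on
chromosomes 4–5, so the contrast is out-of-chromosome generalization, not
in-sample fit.

## Island calling and PLADs

Windows of W = 500 bp are scored against a matched control with an exact
conditional binomial test: given the pooled treatment+control count of a
window, the treatment count is tested against the null proportion equal to
the treatment library's share of total depth. The conditional test is used
instead of a Poisson test against the depth-scaled control value because
the control is itself a noisy sample — treating it as an exact rate floods
a null comparison with false islands (95% of null simulations produce
spurious calls; the conditional test restores validity at any depth).
Windows with upper-tail p < 0.2 (configurable screening level) are
eligible; eligible windows separated by at most G = 1500 bp merge into one
island; island significance is the same binomial test on counts summed over
the island span. Benjamini-Hochberg uses twice the number of scanned
windows as the family size — the scan effectively tests every single window
plus merged contiguous segments, and anchoring the correction to the island
count alone would ignore that islands are pre-selected for small window
p-values (measured ~5-fold null inflation). With this correction, null
simulations at FDR 0.01 produce ≥1 island in ~1% of runs. Islands called
independently in two replicates are intersected base-pair-wise into PLADs.

Log-ratio tracks are log₂((t + pc)/(s·input + pc)) with pseudocount 1 and
`s` the library-depth ratio (estimated from track totals by default; pass
the known ratio when enrichment may be genome-wide, since total-count
scaling would normalize it away). Windows are assigned to domains or their
1-kb flanks by midpoint, flanks clipped at chromosome ends and neighboring
domains; peak overlap uses any-overlap under 0-based half-open coordinates
(a window abutting a peak end does not overlap). All two-group comparisons
are two-sided Mann-Whitney. qPCR fold enrichment is ΔΔCt with assumed
amplification efficiency 2, normalized to the reference locus (TUB2), which
is 1 by construction.

## Synthetic data: scope and limits

The generators reproduce the statistical structure each analysis stage
assumes, not the physics of the instruments: nuclei are perfect ellipsoids
(sorted 2C nuclei are near-spherical) with no optical PSF, chromatic
aberration or nucleoli; radial placement is an exponential boundary-bias
law exp(−d/β) chosen because both its β → 0 (boundary shell) and β → ∞
(uniform) limits are analytically checkable — β is a free synthetic
parameter, not an estimate of real NP affinity; Hi-C maps are Poisson
samples of c·(|i−j|+1)^(−α)·(1±s) with a planted checkerboard, so
compartment strength is a single dial s with no TADs, loops or replicate
structure; sequencing noise is Poisson (no overdispersion), which is
sufficient for the calibration and recovery properties tested. Passing
tests therefore demonstrate correctness and calibration of the procedures
under their stated assumptions, not robustness to optical artifacts,
copy-number variation or library-specific biases.

Default study conditions: spheres of radius 2.5 μm at 0.1 μm voxels
(0.05 μm for morphology accuracy checks); ~50 spots per FISH channel and
β = 0.3 μm for the periphery-biased class; Hi-C at 250 bins × 20 kb,
alternating 10-bin blocks, mean depth 100; regression at 120 windows × 5
chromosomes with 4–30 features and snr 3; tracks over 1 Mb at depth
20/window with 8 planted 10-kb domains at fold 8. The reference experiment
sizes (50 oracle masks, 1000 calibration pairs, 200 null seeds, 100
power/comparison seeds, 20 recovery seeds) give binomial standard errors
well inside the asserted margins while the whole validation suite runs in
about a minute.

## Known limitations

- Segmentation assumes one dominant nucleus per stack and a bimodal DAPI
  histogram; dim or touching nuclei need upstream cropping.
- The eigenvector method assigns every unmasked bin to A or B; there is no
  "indeterminate" class, and near-degenerate leading eigenvalues are only
  flagged.
- The island caller's family-size correction is conservative by design;
  extremely broad, weak enrichment near the screening threshold may be
  missed at small depths.
- Distances from trilinear interpolation are slightly smoothed within one
  voxel of the boundary; sub-voxel spot localization accuracy is ~0.5 voxel.
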