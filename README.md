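# perilad

Quantitative analysis of chromatin tethering at the plant nuclear periphery.

In interphase nuclei, specific genomic regions are anchored at the nuclear
periphery (NP). In *Arabidopsis*, plant lamin-like proteins (CRWN-family) and
non-CG DNA methylation mediate this anchoring; its loss shows up in three
independent read-outs: FISH/chromosome-painting signal moves away from the
DAPI edge, Hi-C maps lose A/B compartment contrast, and lamina-ChIP
enrichment domains (plant lamina-associated domains, PLADs) coincide with
inaccessible, periphery-positioned chromatin. `perilad` implements the
quantitative procedures behind all three read-outs, together with
synthetic-data generators that let every stage be validated end-to-end
without microscopy or sequencing data.

## What it computes

**Radial positioning statistics** (`perilad.imaging`, `perilad.painting`).
A nucleus is a 3D multi-channel stack (DAPI + green/red FISH). The DAPI mask
is segmented (Otsu, largest component, per-slice hole fill) and converted to
an anisotropy-aware Euclidean distance field d(v) to the nuclear boundary.
Per-spot statistics measure the distance of each FISH spot barycenter to the
NP and compare probe classes with a two-sided Mann-Whitney U test (`**` p <
0.01, `*` p < 0.05, `ns` otherwise). Whole-region painting signal is
summarized per nucleus by the cumulative signal fraction within distance d of
the NP; P₀.₅ — the fraction within 0.5 μm — is compared between paired
green/red channels with a Wilcoxon signed-rank test. Nuclear morphology
reports volume and Wadell sphericity ψ = π^(1/3)(6V)^(2/3)/A.

**Hi-C compartmentalization** (`perilad.hic`). Contact matrices are balanced
by iterative correction (ICE, marginal deviation below 1e-4), distance-
normalized (O/E, per-diagonal mean 1), row-correlated, and split into A/B
compartments by the leading eigenvector of the correlation matrix (sign
oriented against a user track). Compartment strength is the mean O/E over
cross-compartment pairs within 1 Mb — near 0 for sharply separated
compartments, near 1 when A and B mix — compared between genotypes by
Mann-Whitney. Inter-chromosomal contact fractions quantify trans contacts.

**NP-interaction regression** (`perilad.regression`). Periphery-interaction
signal (RE-ChIP-like) per genomic window is modelled from epigenomic
features by LASSO with internal standardization, a 100-point log-spaced λ
grid, tenfold cross-validation and the one-standard-error rule (λ.1se).
Adding each window's distance to the nearest pericentromeric region (PR) as
a feature and comparing held-out MSE (train chr1–3, test chr4–5) tests
whether PR proximity explains NP interaction beyond chromatin state.

**PLAD calling** (`perilad.domains`). Broad lamina-ChIP enrichment is called
with a window/gap island scheme (W = 500 bp windows, gaps ≤ G = 1500 bp
merged, FDR < 0.01 by Benjamini-Hochberg): windows are screened with an
exact conditional binomial test against the control, merged into islands,
and island significance is the same test on summed counts. Islands shared
between two replicates (base-pair intersection) are PLADs. Companion
operations compute base-pair Jaccard overlap, log₂ ratio tracks,
accessibility inside domains vs 1-kb flanks, ChIP signal stratified by
ATAC-peak overlap, and ΔΔCt qPCR fold enrichment normalized to TUB2.

**Synthetic data** (`perilad.synthetic`). Ellipsoidal nuclei with uniform or
periphery-biased (acceptance ∝ exp(−d/β)) signal placement, checkerboard
Hi-C maps with power-law decay and tunable compartment strength s ∈ [0, 1],
linear feature-driven responses, and Poisson ChIP tracks with planted
enrichment domains. All generators are pure functions of their seed.

## Worked example

Twelve synthetic nuclei with periphery-biased green signal (β = 0.3 μm) and
uniform red signal, run through segmentation, spot detection and the painting
statistics:

```python
import numpy as np
from perilad import synthetic as sy, imaging as im, painting as pt

spec = sy.NucleusSpec()          # ~spherical 2C nucleus, R = 2.5 um
pairs, green_d, red_d = [], [], []
for k in range(12):
    img = sy.make_nucleus(spec)
    sy.scatter_channel(img, 40, sy.RadialModel("boundary_bias", beta_um=0.3),
                       "green", seed=2 * k)
    sy.scatter_channel(img, 40, sy.RadialModel("uniform"), "red", seed=2 * k + 1)
    im.segment_nucleus(img)
    field = im.boundary_distance_field(img.mask, img.voxel_size_um)
    g = pt.cumulative_signal_profile(img, "green", field)
    r = pt.cumulative_signal_profile(img, "red", field)
    pairs.append((g, r))
    green_d += [s.distance_to_np_um for s in im.detect_spots(img, "green", field=field)]
    red_d += [s.distance_to_np_um for s in im.detect_spots(img, "red", field=field)]

cmp = im.compare_probe_distances(green_d, red_d)
print(f"green spots: {cmp.summary('a')}   red spots: {cmp.summary('b')}")
print(f"Mann-Whitney U = {cmp.u_statistic:.0f}, p = {cmp.p_value:.2e} ({cmp.code})")
res = pt.paired_p05_test(pairs)
p05 = np.asarray(res.pairs)
print(f"mean P0.5: green {p05[:,0].mean():.2f}, red {p05[:,1].mean():.2f}")
print(f"Wilcoxon signed-rank p = {res.p_value:.4f} "
      f"({res.n_green_gt_red}/12 nuclei with green > red)")
```

Output:

```
green spots: 0.33 ± 0.22, 368   red spots: 0.66 ± 0.46, 382
Mann-Whitney U = 37059, p = 3.95e-29 (**)
mean P0.5: green 0.78, red 0.42
Wilcoxon signed-rank p = 0.0005 (12/12 nuclei with green > red)
```

Green spots sit half as far from the periphery as red spots ("mean ± sd, n"),
and every nucleus has a larger green P₀.₅ — the wild-type pattern. Replacing
the green model with `RadialModel("uniform")` abolishes both differences,
the pattern of a tether-defective mutant.

A thin CLI mirrors the library: `perilad simulate nucleus|hic|tracks|features`,
`perilad fish-dist`, `perilad paint`, `perilad hic balance|compartments|strength|trans`,
`perilad model`, and `perilad plad call|intersect|overlap|accessibility|qpcr`
(see `perilad --help`).

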