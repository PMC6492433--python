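"""Synthetic data generators for every stage of the pipeline.

These generators emulate the statistical structure of the study's raw data so
the full analysis chain is testable without microscopy or sequencing runs:

* ellipsoidal 2C nuclei with a DAPI fill and FISH/painting channels whose
  radial placement is either uniform or biased toward the nuclear periphery;
* intra-chromosomal Hi-C contact matrices with power-law distance decay and a
  block A/B checkerboard of tunable strength;
* periphery-interaction (RE-ChIP-like) responses generated linearly from a
  window-by-feature matrix;
* ChIP-like treatment/control count tracks with planted enrichment domains.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .imaging import NucleusImage, boundary_distance_field
from .intervals import GenomicIntervalSet

__all__ = [
    "NucleusSpec",
    "RadialModel",
    "HiCSimConfig",
    "TrackSimConfig",
    "make_nucleus",
    "sample_spot_centers",
    "scatter_channel",
    "simulate_contact_matrix",
    "simulate_rechip_response",
    "simulate_chip_tracks",
    "simulate_feature_table",
]


# ------------------------------------------------------------------- configs

@dataclass(frozen=True)
class NucleusSpec:
    """Geometry and intensity of a synthetic 2C nucleus.

    Default semi-axes of 2.5 μm give the near-spherical, ~65 μm³ nucleus
    typical of sorted diploid Arabidopsis nuclei; the default voxel size
    (0.2 μm z, 0.1 μm xy) reflects a confocal z-stack.
    """

    semi_axes_um: tuple[float, float, float] = (2.5, 2.5, 2.5)
    voxel_size_um: tuple[float, float, float] = (0.2, 0.1, 0.1)
    dapi_level: float = 200.0
    background_level: float = 10.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        ax = np.asarray(self.semi_axes_um, dtype=float)
        vox = np.asarray(self.voxel_size_um, dtype=float)
        if not (np.all(ax > 0) and np.all(vox > 0)):
            raise ValueError("semi-axes and voxel sizes must be positive")
        if np.any(ax < 2 * vox):
            k = int(np.argmax(~(ax >= 2 * vox)))
            raise ValueError(f"semi-axis {'zyx'[k]} must be at least twice the voxel size")
        if not (np.isfinite(self.dapi_level) and np.isfinite(self.background_level)):
            raise ValueError("intensities must be finite")
        if self.dapi_level <= 0 or self.background_level < 0:
            raise ValueError("dapi_level must be > 0 and background_level >= 0")


@dataclass(frozen=True)
class RadialModel:
    """Radial placement law for FISH/painting signal.

    kind="uniform": spots anywhere in the nuclear interior.
    kind="boundary_bias": candidate positions accepted with probability
    exp(-d / beta_um), d the distance to the nuclear boundary — small beta
    presses the signal against the periphery, large beta recovers uniform.
    """

    kind: str = "uniform"
    beta_um: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "boundary_bias"):
            raise ValueError(f"unknown radial model {self.kind!r}")
        if self.kind == "boundary_bias" and (self.beta_um is None or self.beta_um <= 0):
            raise ValueError("boundary_bias requires beta_um > 0")


@dataclass(frozen=True)
class HiCSimConfig:
    """Block-compartment Hi-C simulator settings.

    Expected counts mu_ij = c * (|i-j|+1)^(-decay_alpha) * (1+s) for same-label
    pairs and (1-s) for cross-label pairs, Poisson-sampled and symmetrized;
    c is set so the expected total is mean_depth * n_bins**2.
    """

    n_bins: int
    bin_size_bp: int
    labels: tuple
    strength_s: float
    decay_alpha: float = 1.0
    mean_depth: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.labels) != self.n_bins:
            raise ValueError("labels length must equal n_bins")
        if not 0.0 <= self.strength_s <= 1.0:
            raise ValueError("strength_s must lie in [0, 1]")
        if self.decay_alpha <= 0 or self.mean_depth <= 0 or self.bin_size_bp <= 0:
            raise ValueError("decay_alpha, mean_depth and bin_size_bp must be positive")

    @staticmethod
    def alternating_blocks(n_bins: int, block: int, **kw) -> "HiCSimConfig":
        labels = tuple("A" if (i // block) % 2 == 0 else "B" for i in range(n_bins))
        return HiCSimConfig(n_bins=n_bins, labels=labels, **kw)


@dataclass(frozen=True)
class TrackSimConfig:
    """ChIP treatment/control track simulator settings."""

    genome_length_bp: int
    planted_domains: GenomicIntervalSet
    enrichment_fold: float = 8.0
    window_bp: int = 500
    depth: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if self.depth <= 0 or self.window_bp <= 0 or self.genome_length_bp <= 0:
            raise ValueError("depth, window_bp and genome_length_bp must be positive")
        df = self.planted_domains.df
        if len(df) and (df["start"].min() < 0 or df["end"].max() > self.genome_length_bp):
            raise ValueError("planted domains must lie within [0, genome_length_bp)")


# ------------------------------------------------------------------- nucleus

def make_nucleus(spec: NucleusSpec, dims: tuple[int, int, int] | None = None,
                 margin_voxels: int = 3) -> NucleusImage:
    """Render an axis-aligned ellipsoidal nucleus into a voxel grid.

    The DAPI channel takes ``dapi_level`` inside the ellipsoid and
    ``background_level`` outside (plus optional Poisson noise); the analytic
    interior is attached as the image mask.  If ``dims`` is given and cannot
    contain the ellipsoid, an error names the first offending axis.
    """
    ax = np.asarray(spec.semi_axes_um, dtype=float)
    vox = np.asarray(spec.voxel_size_um, dtype=float)
    need = np.ceil(2 * ax / vox).astype(int) + 2 * margin_voxels
    if dims is None:
        dims = tuple(int(n) for n in need)
    else:
        for k in range(3):
            if dims[k] < need[k] - 2 * margin_voxels:
                raise ValueError(f"ellipsoid exceeds grid along axis {'zyx'[k]}: "
                                 f"need {need[k] - 2 * margin_voxels} voxels, got {dims[k]}")
    centre = 0.5 * np.asarray(dims) * vox
    grids = np.meshgrid(*[(np.arange(n) + 0.5) * v for n, v in zip(dims, vox)],
                        indexing="ij", sparse=True)
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, ax))
    interior = q <= 1.0
    dapi = np.where(interior, spec.dapi_level, spec.background_level).astype(float)
    if spec.poisson_noise:
        rng = np.random.default_rng(spec.seed)
        dapi = rng.poisson(dapi).astype(float)
    zeros = np.zeros(dims, dtype=float)
    return NucleusImage(
        voxel_size_um=tuple(vox),
        channels={"dapi": dapi, "green": zeros.copy(), "red": zeros.copy()},
        mask=interior,
    )


def sample_spot_centers(
    mask: np.ndarray,
    voxel_size_um,
    n_spots: int,
    model: RadialModel,
    rng: np.random.Generator,
    max_batches: int = 2000,
    field: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample spot centres in the mask interior under a radial model.

    Candidates are drawn uniformly over interior voxels (jittered within the
    voxel); for boundary_bias a candidate whose voxel sits at boundary
    distance d is accepted with probability exp(-d / beta).  Returns
    (centers_um (n,3) in zyx, distances_um (n,)).  Raises if the acceptance
    loop exceeds ``max_batches`` rounds.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask has no interior")
    if n_spots == 0:
        return np.empty((0, 3)), np.empty(0)
    vox = np.asarray(voxel_size_um, dtype=float)
    if field is None:
        field = boundary_distance_field(mask, tuple(vox)).values
    interior = np.argwhere(mask)
    d_interior = field[mask]
    centers, dists = [], []
    got = 0
    batch = max(4 * n_spots, 256)
    for _ in range(max_batches):
        idx = rng.integers(0, len(interior), size=batch)
        cand = interior[idx]
        d = d_interior[idx]
        if model.kind == "boundary_bias":
            # acceptance ∝ exp(-d/beta); rescale the envelope so the most
            # peripheral voxels accept with probability 1 (pure efficiency,
            # the target density is unchanged)
            keep = rng.random(batch) < np.exp(-(d - d_interior.min()) / model.beta_um)
            cand, d = cand[keep], d[keep]
        if len(cand):
            jitter = rng.random((len(cand), 3))
            centers.append((cand + jitter) * vox)
            dists.append(d)
            got += len(cand)
        if got >= n_spots:
            break
    else:
        raise RuntimeError("acceptance sampling exceeded the retry cap; beta too small for this mask?")
    centers = np.concatenate(centers)[:n_spots]
    dists = np.concatenate(dists)[:n_spots]
    return centers, dists


def scatter_channel(
    img: NucleusImage,
    n_spots: int,
    model: RadialModel,
    channel: str = "green",
    spot_sigma_um: float = 0.15,
    seed: int = 0,
) -> NucleusImage:
    """Scatter Gaussian signal spots into a channel under a radial model.

    Each spot is a 3D Gaussian blob of total intensity 1 centred at a sampled
    position.  The channel is overwritten in place and the image returned.
    """
    if img.mask is None:
        raise ValueError("image needs a mask before scattering signal")
    rng = np.random.default_rng(seed)
    out = np.zeros(img.shape, dtype=float)
    if n_spots > 0:
        centers, _ = sample_spot_centers(img.mask, img.voxel_size_um, n_spots, model, rng)
        vox = np.asarray(img.voxel_size_um)
        sigma_vox = spot_sigma_um / vox
        half = np.maximum(np.ceil(4 * sigma_vox).astype(int), 1)
        offs = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
        offs = np.stack([o.ravel() for o in offs], axis=1)
        for c in centers:
            cv = c / vox - 0.5  # fractional voxel-centre coordinates
            base = np.round(cv).astype(int)
            pos = base + offs
            ok = np.all((pos >= 0) & (pos < np.array(img.shape)), axis=1)
            pos = pos[ok]
            delta = (pos - cv) * vox
            w = np.exp(-0.5 * np.sum((delta / spot_sigma_um) ** 2, axis=1))
            w /= w.sum()
            np.add.at(out, tuple(pos.T), w)
    img.channels[channel] = out
    return img


# ----------------------------------------------------------------------- HiC

def expected_contact_matrix(cfg: HiCSimConfig) -> np.ndarray:
    """Expected (pre-sampling) contact matrix mu for a config (zero diagonal)."""
    i = np.arange(cfg.n_bins)
    sep = np.abs(i[:, None] - i[None, :])
    decay = (sep + 1.0) ** (-cfg.decay_alpha)
    lab = np.asarray(cfg.labels)
    same = lab[:, None] == lab[None, :]
    mu = decay * np.where(same, 1.0 + cfg.strength_s, 1.0 - cfg.strength_s)
    np.fill_diagonal(mu, 0.0)
    total = mu.sum()
    if total > 0:
        mu *= cfg.mean_depth * cfg.n_bins ** 2 / total
    return mu


def simulate_contact_matrix(cfg: HiCSimConfig):
    """Poisson-sample a symmetric contact matrix with block A/B structure."""
    from .hic import ContactMatrix  # local import to avoid a cycle

    mu = expected_contact_matrix(cfg)
    rng = np.random.default_rng(cfg.seed)
    upper = np.triu(rng.poisson(mu), k=1)
    counts = upper + upper.T
    starts = np.arange(cfg.n_bins) * cfg.bin_size_bp
    return ContactMatrix(
        counts=counts.astype(float),
        bin_size_bp=cfg.bin_size_bp,
        chroms=np.array(["chr1"] * cfg.n_bins),
        starts=starts,
    )


# ------------------------------------------------------------------- tracks

def simulate_rechip_response(X, coefficients, noise_sd: float, seed: int = 0) -> np.ndarray:
    """Linear response y = X @ coefficients + N(0, noise_sd) per window."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(coefficients, dtype=float)
    if X.shape[1] != len(beta):
        raise ValueError(f"coefficient length {len(beta)} != feature count {X.shape[1]}")
    rng = np.random.default_rng(seed)
    y = X @ beta
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    return y


def domain_window_fractions(domains: GenomicIntervalSet, genome_length_bp: int,
                            window_bp: int, chrom: str = "chr1") -> np.ndarray:
    """Per-window fraction of the window covered by domains."""
    n_win = genome_length_bp // window_bp
    frac = np.zeros(n_win)
    starts, ends = domains.arrays(chrom)
    for s, e in zip(starts, ends):
        w0, w1 = int(s) // window_bp, (int(e) - 1) // window_bp
        for w in range(w0, min(w1, n_win - 1) + 1):
            lo, hi = max(s, w * window_bp), min(e, (w + 1) * window_bp)
            frac[w] += (hi - lo) / window_bp
    return np.clip(frac, 0.0, 1.0)


def simulate_chip_tracks(cfg: TrackSimConfig):
    """Poisson treatment/control window-count tracks with planted enrichment.

    Treatment rate is depth outside planted domains and depth*enrichment_fold
    inside, interpolated by covered fraction for windows partially covered;
    control is Poisson(depth) everywhere.
    """
    from .domains import SignalTrack  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    frac = domain_window_fractions(cfg.planted_domains, cfg.genome_length_bp, cfg.window_bp)
    rate_t = cfg.depth * (1.0 + (cfg.enrichment_fold - 1.0) * frac)
    treatment = SignalTrack(chrom="chr1", window_bp=cfg.window_bp,
                            values=rng.poisson(rate_t).astype(float))
    control = SignalTrack(chrom="chr1", window_bp=cfg.window_bp,
                          values=rng.poisson(np.full_like(rate_t, cfg.depth)).astype(float))
    return treatment, control


# ------------------------------------------------------------------ features

def simulate_feature_table(
    n_windows_per_chrom: int = 200,
    n_features: int = 6,
    window_bp: int = 20_000,
    n_chroms: int = 5,
    pr_halfwidth_windows: int = 10,
    seed: int = 0,
):
    """Windows, epigenomic-style features and pericentromeric regions.

    Returns (windows_df, X, feature_names, pr_set).  Each chromosome carries
    one central pericentromeric region; features are smooth correlated tracks
    (an AR(1) walk per feature) mimicking integrated epigenetic marks.
    """
    rng = np.random.default_rng(seed)
    rows, X_parts, pr_records = [], [], []
    for c in range(1, n_chroms + 1):
        chrom = f"chr{c}"
        starts = np.arange(n_windows_per_chrom) * window_bp
        for s in starts:
            rows.append((chrom, int(s), int(s + window_bp)))
        eps = rng.normal(size=(n_windows_per_chrom, n_features))
        x = np.empty_like(eps)
        x[0] = eps[0]
        for t in range(1, n_windows_per_chrom):
            x[t] = 0.7 * x[t - 1] + np.sqrt(1 - 0.7 ** 2) * eps[t]
        X_parts.append(x)
        mid = n_windows_per_chrom // 2
        pr_records.append((chrom, int((mid - pr_halfwidth_windows) * window_bp),
                           int((mid + pr_halfwidth_windows) * window_bp)))
    import pandas as pd

    windows = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    X = np.vstack(X_parts)
    names = [f"mark_{k+1}" for k in range(n_features)]
    return windows, X, names, GenomicIntervalSet.from_records(pr_records)
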