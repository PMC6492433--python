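"""Reference experiments at the package's standard study conditions.

Each function runs one self-contained simulation experiment — the conditions
(sample sizes, depths, effect sizes) are the package's defaults for validating
the corresponding analysis stage — and returns summary statistics as a dict.
They back both the validation test suite and the reproduction script; every
number they emit is computed at call time from the given seed.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from . import domains as dm
from . import hic as hc
from . import imaging as im
from . import painting as pt
from . import regression as rg
from . import synthetic as sy
from .intervals import GenomicIntervalSet

__all__ = [
    "distance_field_oracle",
    "shell_law",
    "probe_test_calibration",
    "positioning_power",
    "hic_suite",
    "lasso_suite",
    "island_caller_suite",
    "plad_end_to_end",
]


# ------------------------------------------------------------------ geometry

def _sphere(voxel: float = 0.1):
    spec = sy.NucleusSpec(semi_axes_um=(2.5, 2.5, 2.5), voxel_size_um=(voxel,) * 3)
    img = sy.make_nucleus(spec)
    field = im.boundary_distance_field(img.mask, img.voxel_size_um)
    return img, field


def distance_field_oracle(seed: int = 0, n_masks: int = 50, size: int = 20) -> dict:
    """Distance field vs exhaustive nearest-outside-voxel search on random masks."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    max_diff = 0.0
    n_exact = 0
    for k in range(n_masks):
        shape = tuple(rng.integers(6, size + 1, size=3))
        voxel = tuple(rng.uniform(0.05, 0.3, size=3))
        smooth = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0)
        mask = smooth > np.quantile(smooth, rng.uniform(0.5, 0.85))
        if not mask.any() or mask.all():
            mask = np.zeros(shape, dtype=bool)
            mask[tuple(s // 2 for s in shape)] = True
        f = im.boundary_distance_field(mask, voxel).values
        vox = np.asarray(voxel)
        inside = np.argwhere(mask) * vox
        outside = np.argwhere(~mask) * vox
        oracle = cdist(inside, outside).min(axis=1)
        diff = float(np.max(np.abs(f[mask] - oracle)))
        max_diff = max(max_diff, diff)
        n_exact += diff < 1e-9
    return {"n_masks": n_masks, "n_exact": n_exact, "max_abs_diff_um": max_diff}


def shell_law(voxel: float = 0.1) -> dict:
    """P0.5 of uniform vs boundary-confined signal in a digital R=2.5 μm sphere."""
    img, field = _sphere(voxel)
    img.channels["green"] = img.mask.astype(float)
    uniform = pt.cumulative_signal_profile(img, "green", field, exclude_bottom_slices=0)
    img.channels["red"] = (img.mask & (field.values <= 0.3)).astype(float)
    boundary = pt.cumulative_signal_profile(img, "red", field, exclude_bottom_slices=0)
    return {
        "p05_uniform": uniform.p05,
        "p05_uniform_expected": 1 - (2.0 / 2.5) ** 3,
        "p05_boundary": boundary.p05,
    }


# -------------------------------------------------------------- calibrations

def probe_test_calibration(seed: int = 0, n_pairs: int = 1000, n_spots: int = 50,
                           n_experiments: int = 200, n_nuclei: int = 20,
                           paint_spots: int = 200, alpha: float = 0.05) -> dict:
    """Type-I error of the two positional tests under matched radial models.

    (1) Mann-Whitney on per-spot distances when both channels are uniform:
    the rejection rate at ``alpha`` should sit at the nominal level.
    (2) Paired Wilcoxon on per-nucleus P0.5 when green and red share the same
    radial model (the situation in a tether-defective mutant).
    """
    img, field = _sphere()
    rng = np.random.default_rng(seed)
    uni = sy.RadialModel("uniform")
    rej = 0
    for _ in range(n_pairs):
        _, dg = sy.sample_spot_centers(img.mask, img.voxel_size_um, n_spots, uni, rng,
                                       field=field.values)
        _, dr = sy.sample_spot_centers(img.mask, img.voxel_size_um, n_spots, uni, rng,
                                       field=field.values)
        rej += im.compare_probe_distances(dg, dr).p_value < alpha
    mw_rate = rej / n_pairs

    rej_w = 0
    for _ in range(n_experiments):
        pairs = []
        for _ in range(n_nuclei):
            _, dg = sy.sample_spot_centers(img.mask, img.voxel_size_um, paint_spots,
                                           uni, rng, field=field.values)
            _, dr = sy.sample_spot_centers(img.mask, img.voxel_size_um, paint_spots,
                                           uni, rng, field=field.values)
            pairs.append((pt.p05_from_distances(dg), pt.p05_from_distances(dr)))
        res = pt.paired_p05_test(pairs)
        rej_w += (not res.all_zero_differences) and res.p_value < alpha
    return {
        "mw_rejection_rate": mw_rate,
        "wilcoxon_rejection_rate": rej_w / n_experiments,
        "n_pairs": n_pairs,
        "n_experiments": n_experiments,
    }


def positioning_power(seed: int = 0, n_sims: int = 100, n_spots: int = 50,
                      beta_um: float = 0.3) -> dict:
    """Power to detect periphery-biased green vs uniform red probes.

    Also runs the matched-model contrast (green boundary bias removed, as in
    a tether-defective mutant) to confirm significance disappears.
    """
    img, field = _sphere()
    rng = np.random.default_rng(seed)
    bias = sy.RadialModel("boundary_bias", beta_um)
    uni = sy.RadialModel("uniform")
    hits = 0
    hits_matched = 0
    for _ in range(n_sims):
        _, dg = sy.sample_spot_centers(img.mask, img.voxel_size_um, n_spots, bias, rng,
                                       field=field.values)
        _, dr = sy.sample_spot_centers(img.mask, img.voxel_size_um, n_spots, uni, rng,
                                       field=field.values)
        hits += im.compare_probe_distances(dg, dr).p_value < 0.01
        _, dg2 = sy.sample_spot_centers(img.mask, img.voxel_size_um, n_spots, uni, rng,
                                        field=field.values)
        _, dr2 = sy.sample_spot_centers(img.mask, img.voxel_size_um, n_spots, uni, rng,
                                        field=field.values)
        hits_matched += im.compare_probe_distances(dg2, dr2).p_value < 0.01
    return {"power": hits / n_sims, "matched_model_rate": hits_matched / n_sims,
            "n_sims": n_sims}


# ---------------------------------------------------------------------- HiC

def _truth_call(cfg, masked):
    labels = np.asarray(cfg.labels, dtype=object).copy()
    labels[masked] = "masked"
    ev = np.where(labels == "A", 1.0, -1.0)
    ev[labels == "masked"] = np.nan
    return hc.CompartmentCall(eigenvector=ev, labels=labels, bin_size_bp=cfg.bin_size_bp)


def hic_suite(seed: int = 0, n_bins: int = 250, depth: float = 100.0) -> dict:
    """Balancing accuracy, compartment recovery and strength attenuation.

    Simulates checkerboard contact maps over a range of compartment strengths
    and runs the full balance → O/E → correlation → eigenvector pipeline;
    the cross-compartment O/E statistic is evaluated against the generator's
    (shared) compartment annotation, mirroring a mutant-vs-wild-type contrast
    with a common annotation.
    """
    rng = np.random.default_rng(seed)
    base_seed = int(rng.integers(0, 2**31 - 10))

    # bias inversion on a constructed problem
    n = 100
    A = rng.uniform(1, 5, size=(n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0)
    toy = hc.ContactMatrix(counts=A, bin_size_bp=1000, chroms=np.array(["chr1"] * n),
                           starts=np.arange(n) * 1000)
    M = hc.ice_balance(toy, eps=1e-10, max_iter=3000, mask_fraction=0.0).values
    bias = rng.uniform(0.5, 2.0, size=n)
    biased = hc.ContactMatrix(counts=M * np.outer(bias, bias), bin_size_bp=1000,
                              chroms=toy.chroms, starts=toy.starts)
    rec = hc.ice_balance(biased, eps=1e-6, max_iter=3000, mask_fraction=0.0)
    ratio = rec.bias_vector / bias
    bias_err = float(np.max(np.abs(ratio / ratio.mean() - 1)))

    strengths = {}
    accuracy = {}
    final_eps = []
    ab_sets = {}
    for s in (0.8, 0.6, 0.4, 0.3, 0.2, 0.0, 1.0):
        cfg = sy.HiCSimConfig.alternating_blocks(
            n_bins, 10, bin_size_bp=20_000, strength_s=s, mean_depth=depth,
            seed=base_seed + int(10 * s))
        m = sy.simulate_contact_matrix(cfg)
        b = hc.ice_balance(m)
        final_eps.append(b.final_eps)
        oe = hc.observed_over_expected(b, allow_unconverged=True)
        corr = hc.correlation_matrix(oe)
        track = np.where(np.asarray(cfg.labels) == "A", 1.0, 0.0)
        call = hc.call_compartments(corr, track, bin_size_bp=cfg.bin_size_bp)
        keep = call.labels != "masked"
        truth = np.where(track == 1.0, "A", "B")
        accuracy[s] = float(np.mean(call.labels[keep] == truth[keep]))
        st = hc.compartment_strength(oe, _truth_call(cfg, b.masked),
                                     max_sep_bp=1_000_000)
        strengths[s] = st.mean_AB_relative
        ab_sets[s] = st
    order = [0.8, 0.6, 0.4, 0.2, 0.0]
    monotone = all(strengths[a] < strengths[b] for a, b in zip(order, order[1:]))
    mw_p = hc.compare_compartment_strength(ab_sets[0.3], ab_sets[0.6])
    return {
        "max_final_eps": float(np.max(final_eps)),
        "bias_recovery_rel_err": bias_err,
        "accuracy_s1": accuracy[1.0],
        "accuracy_s0": accuracy[0.0],
        "mean_ab_oe": {s: strengths[s] for s in order},
        "strictly_monotone": monotone,
        "attenuation_mw_p": mw_p,
        "n_bins": n_bins,
    }


# --------------------------------------------------------------------- LASSO

def lasso_suite(seed: int = 0, n_recovery_seeds: int = 20,
                n_compare_seeds: int = 100) -> dict:
    """Sparse-signal recovery, KKT residuals, and the held-out model contrast."""
    rng = np.random.default_rng(seed)
    nonzero_idx = np.array([2, 7, 11, 19, 25])
    nonzero_beta = np.array([2.0, -1.5, 1.0, 3.0, -2.0])
    sign_ok = 0
    kkt_max = 0.0
    for k in range(n_recovery_seeds):
        rs = int(rng.integers(0, 2**31 - 1))
        local = np.random.default_rng(rs)
        X = local.normal(size=(3000, 30))
        beta = np.zeros(30)
        beta[nonzero_idx] = nonzero_beta
        signal = X @ beta
        noise_sd = float(np.std(signal)) / 3.0  # snr 3
        y = sy.simulate_rechip_response(X, beta, noise_sd, seed=rs)
        fit = rg.fit_lasso_cv(X, y, seed=rs)
        kkt_max = max(kkt_max, rg.kkt_violation(X, y, fit, "1se"),
                      rg.kkt_violation(X, y, fit, "min"))
        active = fit.coefficients[nonzero_idx]
        others = np.delete(fit.coefficients, nonzero_idx)
        sign_ok += (np.all(np.sign(active) == np.sign(nonzero_beta))
                    and np.all(others == 0.0))

    full_better = 0
    null_close = 0
    for k in range(n_compare_seeds):
        rs = int(rng.integers(0, 2**31 - 1))
        for dist_coef, bucket in ((-1.5, "signal"), (0.0, "null")):
            windows, X, _, pr = sy.simulate_feature_table(
                n_windows_per_chrom=120, n_features=4, seed=rs)
            dist, _ = rg.distance_to_pr(windows, pr)
            X_full = np.column_stack([X, dist / 1e6])
            beta = np.array([1.0, -0.5, 0.8, 0.0, dist_coef])
            y = sy.simulate_rechip_response(X_full, beta, noise_sd=0.5, seed=rs + 1)
            mse_full, mse_red, delta = rg.compare_feature_sets(
                X_full, X, y, windows["chrom"].to_numpy(),
                ["chr1", "chr2", "chr3"], ["chr4", "chr5"], seed=rs)
            if bucket == "signal":
                full_better += delta > 0
            else:
                null_close += abs(delta) / mse_red < 0.05
    return {
        "kkt_max_violation": kkt_max,
        "sign_recovery_rate": sign_ok / n_recovery_seeds,
        "distance_model_better_rate": full_better / n_compare_seeds,
        "null_distance_close_rate": null_close / n_compare_seeds,
        "n_recovery_seeds": n_recovery_seeds,
        "n_compare_seeds": n_compare_seeds,
    }


# ------------------------------------------------------------------- islands

def _planted_domains(rng, n_domains: int = 8, domain_bp: int = 10_000,
                     genome_bp: int = 1_000_000):
    slots = np.arange(5, genome_bp // domain_bp - 5)
    starts = np.sort(rng.choice(slots, n_domains, replace=False)) * domain_bp
    return GenomicIntervalSet.from_records(
        [("chr1", int(s), int(s + domain_bp)) for s in starts])


def island_caller_suite(seed: int = 0, n_null_seeds: int = 200,
                        genome_bp: int = 1_000_000, depth: float = 20.0) -> dict:
    """Null false-positive rate, planted-domain recovery, and the gap rule."""
    rng = np.random.default_rng(seed)
    empty = GenomicIntervalSet.from_records([])
    fp = 0
    for k in range(n_null_seeds):
        cfg = sy.TrackSimConfig(genome_length_bp=genome_bp, planted_domains=empty,
                                enrichment_fold=1.0, window_bp=500, depth=depth,
                                seed=int(rng.integers(0, 2**31 - 1)))
        t, c = sy.simulate_chip_tracks(cfg)
        fp += len(dm.call_islands(t, c).islands) > 0

    planted = _planted_domains(rng)
    cfg = sy.TrackSimConfig(genome_length_bp=genome_bp, planted_domains=planted,
                            enrichment_fold=8.0, window_bp=500, depth=depth,
                            seed=int(rng.integers(0, 2**31 - 1)))
    t, c = sy.simulate_chip_tracks(cfg)
    call = dm.call_islands(t, c)
    jac = dm.domain_overlap(call.islands, planted)[0] if len(call.islands) else 0.0

    def gap_islands(gap_windows):
        n = 40
        tv = np.full(n, 10.0)
        cv = np.full(n, 10.0)
        tv[[10, 10 + gap_windows + 1]] = 300.0
        return len(dm.call_islands(dm.SignalTrack("chr1", 500, tv),
                                   dm.SignalTrack("chr1", 500, cv)).islands)

    return {
        "null_fp_rate": fp / n_null_seeds,
        "recovery_jaccard": jac,
        "islands_at_gap_1500bp": gap_islands(3),
        "islands_at_gap_2000bp": gap_islands(4),
        "n_null_seeds": n_null_seeds,
    }


# ------------------------------------------------------------------ end-to-end

def plad_end_to_end(seed: int = 0, genome_bp: int = 1_000_000, depth: float = 20.0,
                    fold: float = 8.0) -> dict:
    """Replicated island calling, PLAD intersection, and accessibility contrast.

    Builds a synthetic genome whose planted periphery-associated domains are
    depleted of accessible chromatin: lamina-ChIP replicates are enriched
    inside the domains, the accessibility track is lower inside them, and
    ChIP signal is suppressed at accessible (peak-overlapping) windows.
    """
    rng = np.random.default_rng(seed)
    W = 500
    n_win = genome_bp // W
    planted = _planted_domains(rng)
    frac = sy.domain_window_fractions(planted, genome_bp, W)

    # accessible peaks: 1-kb sites, four of five outside the planted domains
    peak_records = []
    slots = rng.permutation(n_win - 2)
    for w in slots:
        if len(peak_records) >= 50:
            break
        start = int(w) * W
        inside = frac[w] > 0.5
        want_inside = (len(peak_records) % 5) == 4
        if inside == want_inside:
            peak_records.append(("chr1", start, start + 1000))
    peaks = GenomicIntervalSet.from_records(peak_records)
    peak_frac = sy.domain_window_fractions(peaks, genome_bp, W)

    # lamina-ChIP replicates: enrichment in domains, suppressed at peaks
    calls = []
    for rep in range(2):
        rate_t = depth * (1.0 + (fold - 1.0) * frac) * np.where(peak_frac > 0, 0.25, 1.0)
        rep_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
        t = dm.SignalTrack("chr1", W, rep_rng.poisson(rate_t).astype(float))
        c = dm.SignalTrack("chr1", W, rep_rng.poisson(np.full(n_win, depth)).astype(float))
        calls.append(dm.call_islands(t, c))
    plads = dm.intersect_replicates(*calls)
    jac = dm.domain_overlap(plads, planted)[0] if len(plads) else 0.0

    # accessibility: depleted inside the called domains
    atac_rate = np.where(frac > 0.5, 5.0, 20.0) * np.where(peak_frac > 0, 2.0, 1.0)
    atac = dm.SignalTrack("chr1", W, rng.poisson(atac_rate).astype(float))
    access = dm.signal_in_and_flank(atac, plads, flank_bp=1000)

    # ChIP log-ratio stratified by peak overlap within PLADs and flanks
    rate_t = depth * (1.0 + (fold - 1.0) * frac) * np.where(peak_frac > 0, 0.25, 1.0)
    t = dm.SignalTrack("chr1", W, rng.poisson(rate_t).astype(float))
    c = dm.SignalTrack("chr1", W, rng.poisson(np.full(n_win, depth)).astype(float))
    ratio = dm.log_ratio_track(t, c)
    flanks = dm._flank_set(plads, 1000, genome_bp)
    regions = GenomicIntervalSet.from_records(
        plads.df[["chrom", "start", "end"]].itertuples(index=False, name=None))
    region_union = GenomicIntervalSet.from_records(
        list(regions.df[["chrom", "start", "end"]].itertuples(index=False, name=None))
        + list(flanks.df[["chrom", "start", "end"]].itertuples(index=False, name=None)))
    strat = dm.stratify_by_peak_overlap(ratio, region_union, peaks)

    return {
        "plad_planted_jaccard": jac,
        "n_plads": len(plads),
        "accessibility_p": access["p_value"],
        "accessibility_inside_lower": access["mean_inside"] < access["mean_flank"],
        "chip_vs_peaks_p": strat["p_value"],
        "chip_lower_at_peaks": strat["mean_peak"] < strat["mean_nonpeak"],
    }
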