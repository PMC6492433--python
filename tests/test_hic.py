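"""ICE balancing, O/E, correlation, compartment calling and strength statistics."""

import numpy as np
import pytest

from perilad import hic as hc
from perilad import synthetic as sy


def toy_matrix(counts, bin_size=1000, chrom="chr1"):
    n = len(counts)
    return hc.ContactMatrix(counts=np.asarray(counts, dtype=float), bin_size_bp=bin_size,
                            chroms=np.array([chrom] * n), starts=np.arange(n) * bin_size)


def simulate(s, seed=5, n_bins=200, depth=100.0, block=10):
    cfg = sy.HiCSimConfig.alternating_blocks(n_bins, block, bin_size_bp=20_000,
                                             strength_s=s, mean_depth=depth, seed=seed)
    return cfg, sy.simulate_contact_matrix(cfg)


def truth_call(cfg, masked=None):
    labels = np.asarray(cfg.labels, dtype=object).copy()
    if masked is not None:
        labels[masked] = "masked"
    ev = np.where(labels == "A", 1.0, -1.0)
    ev[labels == "masked"] = np.nan
    return hc.CompartmentCall(eigenvector=ev, labels=labels, bin_size_bp=cfg.bin_size_bp)


def pipeline(s, seed=5, n_bins=200, depth=100.0):
    cfg, m = simulate(s, seed=seed, n_bins=n_bins, depth=depth)
    b = hc.ice_balance(m)
    oe = hc.observed_over_expected(b, allow_unconverged=True)
    corr = hc.correlation_matrix(oe)
    track = np.where(np.asarray(cfg.labels) == "A", 1.0, 0.0)
    call = hc.call_compartments(corr, track, bin_size_bp=cfg.bin_size_bp)
    return cfg, b, oe, corr, call


class TestIceBalance:
    def test_already_balanced_unchanged(self):
        n = 8
        counts = np.full((n, n), 5.0)
        np.fill_diagonal(counts, 0.0)
        b = hc.ice_balance(toy_matrix(counts), mask_fraction=0.0)
        assert b.converged and b.n_iter == 1
        off = ~np.eye(n, dtype=bool)
        assert np.allclose(b.values[off] / counts[off], b.values[off][0] / 5.0)

    def test_recovers_constructed_bias(self):
        rng = np.random.default_rng(0)
        n = 100
        A = rng.uniform(1, 5, size=(n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        M = hc.ice_balance(toy_matrix(A), eps=1e-10, max_iter=3000, mask_fraction=0.0).values
        bias = rng.uniform(0.5, 2.0, size=n)
        D = M * np.outer(bias, bias)
        b = hc.ice_balance(toy_matrix(D), eps=1e-6, max_iter=3000, mask_fraction=0.0)
        ratio = b.bias_vector / bias
        assert np.max(np.abs(ratio / ratio.mean() - 1)) < 1e-3
        off = ~np.eye(n, dtype=bool)
        vr = b.values[off] / M[off]
        assert np.max(np.abs(vr / vr.mean() - 1)) < 1e-3

    def test_converged_marginals_within_eps(self):
        _, m = simulate(0.5, seed=1)
        b = hc.ice_balance(m, eps=1e-4)
        assert b.converged
        keep = ~b.masked
        rows = np.nansum(b.values[np.ix_(keep, keep)], axis=1)
        assert np.max(np.abs(rows / rows.mean() - 1)) < 1e-4

    def test_idempotent(self):
        _, m = simulate(0.5, seed=2)
        b1 = hc.ice_balance(m, eps=1e-6, mask_fraction=0.0)
        m2 = toy_matrix(np.nan_to_num(b1.values))
        b2 = hc.ice_balance(m2, eps=1e-4, mask_fraction=0.0)
        assert b2.n_iter == 1
        assert np.nanmax(np.abs(b2.values - b1.values) / np.nanmean(b1.values)) < 1e-4

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            hc.ice_balance(toy_matrix(np.zeros((5, 5))))

    def test_low_coverage_bins_masked(self):
        _, m = simulate(0.3, seed=3)
        m.counts[7, :] = 0.0
        m.counts[:, 7] = 0.0
        b = hc.ice_balance(m, mask_fraction=0.02)
        assert b.masked[7]
        assert np.isnan(b.values[7]).all()


class TestObservedExpected:
    def test_pure_distance_decay_gives_ones(self):
        n = 30
        sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        vals = 7.0 * (sep + 1.0) ** -1.2
        np.fill_diagonal(vals, 0.0)
        b = hc.BalancedMatrix(values=vals, bias_vector=np.ones(n),
                              masked=np.zeros(n, dtype=bool), converged=True,
                              final_eps=0.0, n_iter=0, bin_size_bp=1000,
                              chroms=np.array(["chr1"] * n), starts=np.arange(n) * 1000)
        oe = hc.observed_over_expected(b)
        off = ~np.eye(n, dtype=bool)
        assert np.allclose(oe[off], 1.0)

    def test_per_diagonal_mean_is_one(self):
        _, m = simulate(0.6, seed=7, n_bins=80)
        b = hc.ice_balance(m)
        oe = hc.observed_over_expected(b, allow_unconverged=True)
        for d in range(1, 40):
            diag = np.diagonal(oe, offset=d)
            vals = diag[np.isfinite(diag)]
            if len(vals):
                assert np.mean(vals) == pytest.approx(1.0)

    def test_small_hand_matrix(self):
        """O/E equals an independent per-diagonal hand computation."""
        rng = np.random.default_rng(1)
        n = 6
        A = rng.integers(1, 20, size=(n, n)).astype(float)
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        b = hc.BalancedMatrix(values=A, bias_vector=np.ones(n),
                              masked=np.zeros(n, dtype=bool), converged=True,
                              final_eps=0.0, n_iter=0, bin_size_bp=1000,
                              chroms=np.array(["chr1"] * n), starts=np.arange(n) * 1000)
        oe = hc.observed_over_expected(b)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = abs(i - j)
                exp = np.mean([A[k, k + d] for k in range(n - d)])
                assert oe[i, j] == pytest.approx(A[i, j] / exp)


class TestCorrelationAndCalls:
    def test_perfect_blocks_give_plus_minus_one(self):
        """Idealized two-level O/E: within-block corr +1, cross-block -1."""
        lab = np.array(["A"] * 10 + ["B"] * 10 + ["A"] * 10 + ["B"] * 10)
        same = lab[:, None] == lab[None, :]
        oe = np.where(same, 1.5, 0.5).astype(float)
        np.fill_diagonal(oe, np.nan)
        corr = hc.correlation_matrix(oe)
        off = ~np.eye(len(lab), dtype=bool)
        ok = np.isfinite(corr) & off
        assert np.allclose(corr[ok & same], 1.0)
        assert np.allclose(corr[ok & ~same], -1.0)

    def test_hand_matrix_matches_numpy_pearson(self):
        rng = np.random.default_rng(2)
        oe = rng.random((4, 4))
        oe = (oe + oe.T) / 2
        corr = hc.correlation_matrix(oe, relevel=False)
        ref = np.corrcoef(oe)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(corr[off], ref[off])

    def test_null_correlations_centred_on_zero(self):
        _, _, _, corr, _ = pipeline(0.0, seed=11, n_bins=150, depth=200.0)
        off = ~np.eye(corr.shape[0], dtype=bool)
        vals = corr[off & np.isfinite(corr)]
        assert abs(vals.mean()) < 0.05

    def test_compartment_recovery_and_orientation(self):
        cfg, b, _, _, call = pipeline(1.0, seed=13)
        truth = np.asarray(cfg.labels)
        keep = call.labels != "masked"
        acc = np.mean(call.labels[keep] == truth[keep])
        assert acc >= 0.95
        assert np.all(call.eigenvector[keep & (call.labels == "A")] > 0)

    def test_null_labels_agree_with_truth_at_chance(self):
        accs = []
        for seed in range(5):
            cfg, _, _, _, call = pipeline(0.0, seed=20 + seed, n_bins=150)
            truth = np.asarray(cfg.labels)
            keep = call.labels != "masked"
            accs.append(np.mean(call.labels[keep] == truth[keep]))
        assert 0.4 <= np.mean(accs) <= 0.6


class TestAgreementAndStrength:
    def test_agreement_self_and_flip(self):
        cfg, _, _, _, call = pipeline(0.8, seed=30)
        assert hc.compartment_agreement(call, call) == 1.0
        flipped = hc.CompartmentCall(
            eigenvector=-call.eigenvector,
            labels=np.array(["masked" if l == "masked" else ("B" if l == "A" else "A")
                             for l in call.labels], dtype=object),
            bin_size_bp=call.bin_size_bp)
        assert hc.compartment_agreement(call, flipped) == 0.0

    def test_replicate_simulations_agree(self):
        _, _, _, _, c1 = pipeline(0.8, seed=41)
        _, _, _, _, c2 = pipeline(0.8, seed=42)
        assert hc.compartment_agreement(c1, c2) >= 0.9

    def test_no_compartments_gives_unit_strength(self):
        cfg, m = simulate(0.0, seed=50, n_bins=200)
        b = hc.ice_balance(m)
        oe = hc.observed_over_expected(b, allow_unconverged=True)
        st = hc.compartment_strength(oe, truth_call(cfg, b.masked), max_sep_bp=1_000_000)
        assert 0.95 <= st.mean_AB_relative <= 1.05

    def test_attenuation_direction_between_genotypes(self):
        """Weaker compartmentalization shows higher cross-compartment O/E."""
        results = {}
        for s in (0.6, 0.3):
            cfg, m = simulate(s, seed=60, n_bins=250)
            b = hc.ice_balance(m)
            oe = hc.observed_over_expected(b, allow_unconverged=True)
            results[s] = hc.compartment_strength(oe, truth_call(cfg, b.masked))
        assert results[0.3].mean_AB_relative > results[0.6].mean_AB_relative
        assert hc.compare_compartment_strength(results[0.3], results[0.6]) < 0.01

    def test_single_ab_pair(self):
        oe = np.array([[np.nan, 0.7], [0.7, np.nan]])
        call = hc.CompartmentCall(eigenvector=np.array([1.0, -1.0]),
                                  labels=np.array(["A", "B"], dtype=object),
                                  bin_size_bp=1000)
        st = hc.compartment_strength(oe, call, max_sep_bp=1000)
        assert st.oe_values_AB.tolist() == [pytest.approx(0.7)]


class TestTransContacts:
    def two_chrom(self, cis_a, cis_b, trans):
        counts = np.zeros((4, 4))
        counts[0, 1] = counts[1, 0] = cis_a
        counts[2, 3] = counts[3, 2] = cis_b
        counts[0, 2] = counts[2, 0] = trans
        return hc.ContactMatrix(counts=counts, bin_size_bp=1000,
                                chroms=np.array(["chr1", "chr1", "chr2", "chr2"]),
                                starts=np.array([0, 1000, 0, 1000]))

    def test_block_diagonal_is_cis_only(self):
        overall, _ = hc.trans_contact_fraction(self.two_chrom(10, 10, 0))
        assert overall == 0.0

    def test_all_mass_off_block(self):
        overall, _ = hc.trans_contact_fraction(self.two_chrom(0, 0, 5))
        assert overall == 1.0

    def test_hand_counts(self):
        m = self.two_chrom(30, 10, 10)  # cis 80, trans 20 (both triangles)
        overall, per_pair = hc.trans_contact_fraction(m)
        assert overall == pytest.approx(0.20)
        assert per_pair[("chr1", "chr2")] == pytest.approx(0.20)
        assert sum(per_pair.values()) == pytest.approx(1.0)
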