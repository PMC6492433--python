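"""Window binning, island calling, replicate intersection, ratio tracks, qPCR."""

import numpy as np
import pandas as pd
import pytest

from perilad import domains as dm
from perilad import synthetic as sy
from perilad.intervals import GenomicIntervalSet


def null_tracks(seed, genome=1_000_000, depth=20.0):
    cfg = sy.TrackSimConfig(genome_length_bp=genome,
                            planted_domains=GenomicIntervalSet.from_records([]),
                            enrichment_fold=1.0, window_bp=500, depth=depth, seed=seed)
    return sy.simulate_chip_tracks(cfg)


def planted_setup(fold, seed=11, genome=1_000_000, depth=20.0):
    rng = np.random.default_rng(7)
    starts = np.sort(rng.choice(np.arange(5, 95), 8, replace=False)) * 10_000
    planted = GenomicIntervalSet.from_records(
        [("chr1", int(s), int(s + 10_000)) for s in starts])
    cfg = sy.TrackSimConfig(genome_length_bp=genome, planted_domains=planted,
                            enrichment_fold=fold, window_bp=500, depth=depth, seed=seed)
    t, c = sy.simulate_chip_tracks(cfg)
    return planted, t, c


class TestWindowCounts:
    def test_read_binning(self):
        track = dm.window_counts(np.array([10, 200, 499]), W_bp=500, genome_length_bp=2000)
        assert track.values.tolist() == [3, 0, 0, 0]

    def test_bedgraph_constant_mean(self):
        bg = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [5000], "value": [2.0]})
        track = dm.window_counts(bg, W_bp=500, genome_length_bp=5000, mode="bedgraph")
        assert np.allclose(track.values, 2.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_per_read_binning(self, seed):
        rng = np.random.default_rng(seed)
        reads = rng.integers(0, 10_000, size=300)
        track = dm.window_counts(reads, W_bp=500, genome_length_bp=10_000)
        expect = np.zeros(20)
        for r in reads:
            expect[r // 500] += 1
        assert np.array_equal(track.values, expect)

    def test_unsorted_reads_warn(self):
        with pytest.warns(UserWarning, match="unsorted"):
            dm.window_counts(np.array([900, 100]), W_bp=500, genome_length_bp=1000)


class TestCallIslands:
    def test_null_rarely_calls_islands(self):
        fp = sum(len(dm.call_islands(*null_tracks(seed)).islands) > 0
                 for seed in range(25))
        assert fp <= 2

    def test_planted_domains_recovered(self):
        planted, t, c = planted_setup(8.0)
        call = dm.call_islands(t, c)
        jac, _, _ = dm.domain_overlap(call.islands, planted)
        assert jac >= 0.9

    def test_recovery_monotone_in_fold(self):
        jacs = []
        for fold in (1.5, 2.0, 4.0, 8.0):
            planted, t, c = planted_setup(fold)
            call = dm.call_islands(t, c)
            jac = dm.domain_overlap(call.islands, planted)[0] if len(call.islands) else 0.0
            jacs.append(jac)
        assert all(b >= a for a, b in zip(jacs, jacs[1:]))

    def test_gap_rule_exact(self):
        """Eligible windows 1500 bp apart merge; 2000 bp apart split (G=1500, W=500)."""

        def tracks(gap_windows):
            n = 40
            t = np.full(n, 10.0)
            c = np.full(n, 10.0)
            hot = [10, 10 + gap_windows + 1]
            t[hot] = 300.0
            return (dm.SignalTrack("chr1", 500, t), dm.SignalTrack("chr1", 500, c))

        merged = dm.call_islands(*tracks(3))     # gap = 3 * 500 = 1500 bp
        assert len(merged.islands) == 1
        split = dm.call_islands(*tracks(4))      # gap = 2000 bp
        assert len(split.islands) == 2

    def test_empty_eligible_set_is_not_an_error(self):
        t = dm.SignalTrack("chr1", 500, np.full(50, 5.0))
        c = dm.SignalTrack("chr1", 500, np.full(50, 500.0))
        call = dm.call_islands(t, c)
        assert len(call.islands) == 0

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            dm.call_islands(dm.SignalTrack("chr1", 500, np.ones(10)),
                            dm.SignalTrack("chr1", 200, np.ones(10)))


class TestReplicatesAndOverlap:
    def test_identical_sets_unchanged(self):
        a = GenomicIntervalSet.from_records([("chr1", 0, 100), ("chr1", 500, 900)])
        assert dm.intersect_replicates(a, a).df.equals(a.df)

    def test_disjoint_sets_empty(self):
        a = GenomicIntervalSet.from_records([("chr1", 0, 100)])
        b = GenomicIntervalSet.from_records([("chr1", 200, 300)])
        assert len(dm.intersect_replicates(a, b)) == 0

    def test_partial_overlap(self):
        a = GenomicIntervalSet.from_records([("chr1", 100, 500)])
        b = GenomicIntervalSet.from_records([("chr1", 300, 800)])
        out = dm.intersect_replicates(a, b)
        assert out.df[["start", "end"]].to_numpy().tolist() == [[300, 500]]

    def test_intersection_subset_of_both(self):
        rng = np.random.default_rng(3)
        a = GenomicIntervalSet.from_records(
            [("chr1", int(s), int(s + rng.integers(50, 500))) for s in rng.choice(10_000, 10)])
        b = GenomicIntervalSet.from_records(
            [("chr1", int(s), int(s + rng.integers(50, 500))) for s in rng.choice(10_000, 10)])
        inter = dm.intersect_replicates(a, b)
        assert inter.intersect(a).total_bp() == inter.total_bp()
        assert inter.intersect(b).total_bp() == inter.total_bp()


class TestLogRatio:
    def test_equal_tracks_zero(self):
        t = dm.SignalTrack("chr1", 500, np.array([5.0, 10.0, 20.0]))
        out = dm.log_ratio_track(t, dm.SignalTrack("chr1", 500, t.values.copy()))
        assert np.allclose(out.values, 0.0)

    def test_fourfold_enrichment_near_two(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(1000, 200).astype(float)
        t = dm.SignalTrack("chr1", 500, 4.0 * base)
        i = dm.SignalTrack("chr1", 500, base)
        out = dm.log_ratio_track(t, i, scale=1.0)  # equal sequencing depths
        assert np.mean(out.values) == pytest.approx(2.0, abs=0.05)

    def test_hand_computed_five_windows(self):
        t = dm.SignalTrack("chr1", 500, np.array([0.0, 4.0, 9.0, 1.0, 6.0]))
        i = dm.SignalTrack("chr1", 500, np.array([0.0, 4.0, 3.0, 7.0, 6.0]))
        out = dm.log_ratio_track(t, i, pseudocount=1.0)
        s = 20.0 / 20.0
        expect = np.log2((t.values + 1) / (s * i.values + 1))
        assert np.isnan(out.values[0])  # both zero -> masked
        assert np.allclose(out.values[1:], expect[1:])

    def test_grid_mismatch_errors(self):
        with pytest.raises(ValueError):
            dm.log_ratio_track(dm.SignalTrack("chr1", 500, np.ones(5)),
                               dm.SignalTrack("chr1", 500, np.ones(6)))


class TestInFlankAndStratify:
    def setup_track(self, values):
        return dm.SignalTrack("chr1", 500, np.asarray(values, dtype=float))

    def test_constant_track_no_difference(self):
        doms = GenomicIntervalSet.from_records([("chr1", 5000, 10_000)])
        res = dm.signal_in_and_flank(self.setup_track(np.ones(40)), doms)
        assert res["mean_inside"] == res["mean_flank"]
        assert res["p_value"] > 0.9

    def test_depleted_interior_detected(self):
        vals = np.ones(100)
        doms = GenomicIntervalSet.from_records([("chr1", 10_000, 25_000)])
        vals[20:50] = 0.0  # windows inside the domain
        res = dm.signal_in_and_flank(self.setup_track(vals), doms, flank_bp=1000)
        assert res["p_value"] < 1e-6
        assert res["mean_inside"] < res["mean_flank"]

    def test_domain_at_chromosome_start(self):
        doms = GenomicIntervalSet.from_records([("chr1", 0, 5000)])
        res = dm.signal_in_and_flank(self.setup_track(np.arange(40.0)), doms)
        assert res["n_flank"] == 2  # right flank only

    def test_empty_peaks_flagged(self):
        regions = GenomicIntervalSet.from_records([("chr1", 0, 10_000)])
        res = dm.stratify_by_peak_overlap(self.setup_track(np.ones(20)), regions,
                                          GenomicIntervalSet.from_records([]))
        assert res["undefined"]

    def test_peak_windows_have_lower_signal(self):
        regions = GenomicIntervalSet.from_records([("chr1", 0, 50_000)])
        peaks = GenomicIntervalSet.from_records(
            [("chr1", i * 1000, i * 1000 + 500) for i in range(0, 50, 2)])
        vals = np.ones(100)
        for i in range(100):
            if peaks.overlaps_interval("chr1", i * 500, (i + 1) * 500):
                vals[i] = 0.0
        res = dm.stratify_by_peak_overlap(self.setup_track(vals), regions, peaks)
        assert res["mean_peak"] == 0.0 and res["mean_nonpeak"] == 1.0
        assert res["p_value"] < 1e-6

    def test_abutting_window_not_overlapping(self):
        regions = GenomicIntervalSet.from_records([("chr1", 0, 2000)])
        peaks = GenomicIntervalSet.from_records([("chr1", 500, 1000)])
        vals = np.array([1.0, 0.0, 1.0, 1.0])
        res = dm.stratify_by_peak_overlap(self.setup_track(vals), regions, peaks)
        # only window [500,1000) overlaps; [1000,1500) abuts and does not
        assert res["n_peak"] == 1


class TestQPCR:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["locus", "template", "Ct"])

    def test_reference_normalization(self):
        t = self.table([("TUB2", "IP", 28.0), ("TUB2", "input", 24.0),
                        ("L1", "IP", 30.0), ("L1", "input", 26.0),
                        ("L2", "IP", 26.0), ("L2", "input", 24.0)])
        fold = dm.qpcr_fold_enrichment(t)
        assert fold["TUB2"] == pytest.approx(1.0)
        assert fold["L1"] == pytest.approx(1.0)    # same dCt as reference
        assert fold["L2"] == pytest.approx(4.0)    # dCt two cycles smaller

    def test_hand_computed_three_loci(self):
        t = self.table([("TUB2", "IP", 30.0), ("TUB2", "input", 25.0),
                        ("A", "IP", 28.5), ("A", "input", 25.5),
                        ("B", "IP", 33.0), ("B", "input", 26.0)])
        fold = dm.qpcr_fold_enrichment(t)
        assert fold["A"] == pytest.approx(2 ** -(3.0 - 5.0))
        assert fold["B"] == pytest.approx(2 ** -(7.0 - 5.0))

    def test_missing_ct_names_locus(self):
        t = self.table([("TUB2", "IP", 30.0), ("TUB2", "input", 25.0),
                        ("A", "IP", 28.5)])
        with pytest.raises(ValueError, match="A"):
            dm.qpcr_fold_enrichment(t)
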