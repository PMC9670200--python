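import numpy as np
import pytest

from acetydyn import synth
from acetydyn.core import GenomicInterval
from acetydyn.domains import call_domains
from acetydyn.profiles import (
    build_domain_signal_matrix,
    classify_peak_response,
    classify_peaks_by_tss,
    cluster_domain_transitions,
    correlate_tracks,
    gene_density_correlation,
    metagene_profile,
    tss_profile,
)


class TestClustering:
    def test_recovers_planted_two_level_partition(self):
        # exhaustive-assignment oracle on 10 rows: the optimal 2-means
        # split of constant rows at 10 and 0 is the planted partition
        rows = np.vstack([np.full((5, 8), 10.0), np.zeros((5, 8))])
        labels, profiles, _ = cluster_domain_transitions(rows, k=2, seed=0)
        assert labels.tolist() == [0] * 5 + [1] * 5  # 0 = strongest cluster
        assert np.allclose(profiles[0], 10.0)
        assert np.allclose(profiles[1], 0.0)

    def test_identical_rows_degenerate_not_error(self):
        rows = np.full((6, 4), 3.0)
        labels, _, inertia = cluster_domain_transitions(rows, k=2, seed=0)
        assert inertia == pytest.approx(0.0)
        assert len(np.unique(labels)) <= 2

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        rows = np.vstack([rng.normal(10, 0.1, (6, 5)), rng.normal(0, 0.1, (6, 5))])
        perm = rng.permutation(12)
        l1, _, _ = cluster_domain_transitions(rows, k=2, seed=0)
        l2, _, _ = cluster_domain_transitions(rows[perm], k=2, seed=0)
        assert np.array_equal(l1[perm], l2)

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError):
            cluster_domain_transitions(np.zeros((2, 4)), k=3)

    def test_matrix_from_domains_has_layers(self, genome, stage_params):
        _m, _p, gv = synth.generate_stage_tracks(genome, stage_params["GV"], seed=31)
        doms = call_domains(gv, 1000)
        mat = build_domain_signal_matrix(doms, {"GV": gv}, flank=10_000, n_bins=50)
        assert mat.shape == (len(doms), 50)
        # domain centers sit on the plateau
        assert (mat[:, 25] >= 3).all()


class TestCorrelations:
    def test_self_correlation_is_one(self, track_factory):
        rng = np.random.default_rng(1)
        t = track_factory({"chr1": rng.uniform(0, 5, 50)}, bin_size=5000)
        assert correlate_tracks(t, t) == pytest.approx(1.0)

    def test_antitone_spearman_minus_one(self, track_factory):
        vals = np.arange(1.0, 21.0)
        a = track_factory({"chr1": vals}, bin_size=5000)
        b = track_factory({"chr1": vals.max() - vals + 1}, bin_size=5000)
        assert correlate_tracks(a, b) == pytest.approx(-1.0)

    def test_matches_rank_formula_on_hand_table(self, track_factory):
        av = [1.0, 4.0, 2.0, 7.0, 5.0, 3.0]
        bv = [2.0, 3.0, 1.0, 8.0, 6.0, 4.0]
        a = track_factory({"chr1": av}, bin_size=5000)
        b = track_factory({"chr1": bv}, bin_size=5000)
        # direct Spearman: 1 - 6*sum(d^2)/(n(n^2-1)) on distinct ranks
        ra = np.argsort(np.argsort(av))
        rb = np.argsort(np.argsort(bv))
        d2 = ((ra - rb) ** 2).sum()
        expect = 1 - 6 * d2 / (6 * 35)
        assert correlate_tracks(a, b) == pytest.approx(expect)

    def test_double_zero_bins_excluded(self, track_factory):
        a = track_factory({"chr1": [0, 0, 0, 1, 2, 3]}, bin_size=5000)
        b = track_factory({"chr1": [0, 0, 0, 2, 4, 6]}, bin_size=5000)
        assert correlate_tracks(a, b) == pytest.approx(1.0)

    def test_too_few_bins_raises(self, track_factory):
        a = track_factory({"chr1": [0.0, 1.0]}, bin_size=5000)
        with pytest.raises(ValueError, match="fewer than 3"):
            correlate_tracks(a, a)


class TestGeneDensity:
    def test_genes_in_domains_correlate(self, genome):
        params = synth.StageParams(
            "zygote", "broad", 30, (20_000, 80_000), 6.0, 0.0,
            allelic_asymmetry=1.8, paternal_widen=0.25,
        )
        _m, _p, zy = synth.generate_stage_tracks(genome, params, seed=32)
        # plant genes only inside domains: gene density follows signal
        from acetydyn.core import Gene

        genes = []
        for i, (iv, _l) in enumerate(genome.truth.planted_domains[("zygote", "maternal")]):
            for k, tss in enumerate(range(iv.start, iv.end, 10_000)):
                genes.append(Gene(f"d{i}_{k}", iv.chrom, tss, tss + 1000, "+"))
        r = gene_density_correlation(zy, genes, window=100_000)
        assert r > 0.9

    def test_constant_track_raises(self, track_factory, gene_factory):
        t = track_factory({"chr1": [2.0] * 200})
        genes = [gene_factory("g", "chr1", 5000, 9000)]
        with pytest.raises(ValueError, match="constant"):
            gene_density_correlation(t, genes, window=100_000)

    def test_window_merge_consistent_with_recount(self, genome, stage_params):
        _m, _p, zy = synth.generate_stage_tracks(genome, stage_params["zygote"], seed=33)
        genes = genome.genes
        # recount oracle: counts at 200 kb equal pairwise sums of 100 kb counts
        def counts(window):
            out = []
            for chrom in zy.chroms:
                tss = np.array([g.tss for g in genes if g.chrom == chrom])
                for s in range(0, zy.chrom_sizes[chrom], window):
                    out.append(int(((tss >= s) & (tss < s + window)).sum()))
            return out

        c100 = counts(100_000)
        c200 = counts(200_000)
        per_chrom = len(c100) // 2
        for ci in range(2):
            a = c100[ci * per_chrom : (ci + 1) * per_chrom]
            b = c200[ci * 25 : (ci + 1) * 25]
            assert [a[2 * i] + a[2 * i + 1] for i in range(len(b))] == b


class TestMetaProfiles:
    def test_uniform_track_flat_profile(self, track_factory, gene_factory):
        t = track_factory({"chr1": [4.0] * 100})
        genes = [gene_factory("g", "chr1", 30_000, 60_000)]
        prof = metagene_profile(t, genes, body_bins=10, flank=5000, flank_bins=5)
        assert np.allclose(prof.values, 4.0)

    def test_step_track_matches_per_base_oracle(self, track_factory, gene_factory):
        vals = np.concatenate([np.full(30, 2.0), np.full(70, 8.0)])
        t = track_factory({"chr1": vals})
        g = gene_factory("g", "chr1", 20_000, 40_000, "+")
        prof = metagene_profile(t, [g], body_bins=10, flank=10_000, flank_bins=10)
        per_base = np.repeat(vals, 1000)
        oracle = [per_base[10_000 + i * 1000 : 10_000 + (i + 1) * 1000].mean() for i in range(10)]
        oracle += [per_base[20_000 + i * 2000 : 20_000 + (i + 1) * 2000].mean() for i in range(10)]
        oracle += [per_base[40_000 + i * 1000 : 40_000 + (i + 1) * 1000].mean() for i in range(10)]
        assert np.allclose(prof.values, oracle)

    def test_minus_strand_mirrors(self, track_factory, gene_factory):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 5, 100)
        t = track_factory({"chr1": vals})
        rev = track_factory({"chr1": vals[::-1].copy()})
        plus = gene_factory("g", "chr1", 30_000, 60_000, "+")
        minus = gene_factory("g", "chr1", 100_000 - 60_000, 100_000 - 30_000, "-")
        p1 = metagene_profile(t, [plus], body_bins=10, flank=5000, flank_bins=5)
        p2 = metagene_profile(rev, [minus], body_bins=10, flank=5000, flank_bins=5)
        assert np.allclose(p1.values, p2.values)

    def test_short_genes_skipped_and_counted(self, track_factory, gene_factory):
        t = track_factory({"chr1": [1.0] * 100})
        genes = [
            gene_factory("long", "chr1", 10_000, 40_000),
            gene_factory("short", "chr1", 50_000, 52_000),
        ]
        prof = metagene_profile(t, genes, body_bins=10, flank=1000, flank_bins=1)
        assert prof.n_genes == 1 and prof.n_skipped == 1

    def test_tss_profile_strand_mirror(self, track_factory, gene_factory):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 5, 100)
        t = track_factory({"chr1": vals})
        rev = track_factory({"chr1": vals[::-1].copy()})
        plus = gene_factory("g", "chr1", 40_000, 50_000, "+")
        minus = gene_factory("g", "chr1", 50_000, 60_000, "-")
        p1 = tss_profile(t, [plus], flank=2000, n_bins=4)
        p2 = tss_profile(rev, [minus], flank=2000, n_bins=4)
        assert np.allclose(p1.values, p2.values)


class TestPeakClassification:
    tss = [("chr1", 10_000)]

    def _peak(self, mid):
        return GenomicInterval("chr1", mid - 100, mid + 100)

    def test_distance_classes(self):
        peaks = [self._peak(10_500), self._peak(13_000), self._peak(11_500)]
        labels = classify_peaks_by_tss(peaks, self.tss)
        assert labels == {0: "promoter", 1: "distal", 2: "other"}

    def test_partition_property(self):
        rng = np.random.default_rng(6)
        peaks = [self._peak(int(m)) for m in rng.integers(500, 99_000, 50)]
        labels = classify_peaks_by_tss(peaks, self.tss)
        assert set(labels) == set(range(50))
        assert set(labels.values()) <= {"promoter", "distal", "other"}

    def test_response_classes(self, track_factory):
        control = track_factory({"chr1": [4.0] * 30})
        treated = track_factory({"chr1": [4.0] * 10 + [0.0] * 10 + [16.0] * 10})
        peaks = [
            GenomicInterval("chr1", 2_000, 4_000),    # unchanged
            GenomicInterval("chr1", 12_000, 14_000),  # to zero -> lost
            GenomicInterval("chr1", 22_000, 24_000),  # 4x gain -> enhanced
        ]
        labels = classify_peak_response(peaks, control, treated)
        assert labels == {0: "unaffected", 1: "lost", 2: "enhanced"}
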