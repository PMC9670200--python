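import math

import numpy as np
import pytest

from acetydyn import synth
from acetydyn.gene_sets import derive_all_gene_sets


class TestGenerateGenome:
    def test_fixed_seed_reproduces_model(self):
        cfg = synth.GenomeConfig(
            n_chromosomes=2, chromosome_length=400_000, n_genes=10,
            repeat_families={"FAM": (3, 100, 150)},
            n_maternal_icrs=2, n_paternal_icrs=1,
            class_sizes={"major_zga": 3},
        )
        a = synth.generate_genome(cfg, seed=7)
        b = synth.generate_genome(cfg, seed=7)
        assert a.sequences == b.sequences
        assert a.genes == b.genes
        assert a.snps == b.snps
        assert a.truth.gene_classes == b.truth.gene_classes

    def test_zero_genes_is_valid(self):
        cfg = synth.GenomeConfig(
            n_chromosomes=1, chromosome_length=200_000, n_genes=0,
            repeat_families={}, n_maternal_icrs=0, n_paternal_icrs=0,
            class_sizes={},
        )
        g = synth.generate_genome(cfg, seed=1)
        assert g.genes == []

    def test_snp_count_within_poisson_bound(self):
        # rate 1/1000 over 10 Mb: expect 10,000 +- 3 sqrt(10,000)
        g = synth.generate_genome(synth.GenomeConfig(), seed=3)
        n = len(g.snps)
        assert abs(n - 10_000) <= 3 * math.sqrt(10_000)

    def test_infeasible_packing_raises(self):
        cfg = synth.GenomeConfig(
            n_chromosomes=1, chromosome_length=50_000, n_genes=100,
            gene_length_range=(5_000, 10_000), repeat_families={},
            n_maternal_icrs=0, n_paternal_icrs=0, class_sizes={},
        )
        with pytest.raises(ValueError, match="crowded"):
            synth.generate_genome(cfg, seed=1)

    def test_gene_classes_are_disjoint(self, genome):
        all_ids = [gid for ids in genome.truth.gene_classes.values() for gid in ids]
        assert len(all_ids) == len(set(all_ids))

    def test_features_within_bounds(self, genome):
        for fam, iv in genome.repeats:
            assert iv.end <= genome.chromosomes[iv.chrom]
        for s in genome.snps:
            assert 0 <= s.pos < genome.chromosomes[s.chrom]
            assert s.maternal_base == genome.sequences[s.chrom][s.pos]


class TestStageTracks:
    def test_zero_noise_is_piecewise_constant(self, genome):
        sp = synth.StageParams("GV", "broad", 10, (20_000, 50_000), 6.0, 0.5)
        m, p, c = synth.generate_stage_tracks(genome, sp, seed=5)
        planted = genome.truth.planted_domains[("GV", "maternal")]
        vals = set()
        for iv, level in planted:
            seg = m.data[iv.chrom][iv.start // 500 : iv.end // 500]
            assert np.all(seg == level)
            vals.add(level)
        # outside domains: background everywhere
        outside = m.data["chr1"].copy()
        for iv, _l in planted:
            if iv.chrom == "chr1":
                outside[iv.start // 500 : iv.end // 500] = 0.5
        assert np.all(outside == 0.5)

    def test_symmetric_alleles_identical(self, genome):
        sp = synth.StageParams("early2C", "canonical", 20, (1_000, 3_000), 8.0, 0.5,
                               call_bin_size=500)
        m, p, c = synth.generate_stage_tracks(genome, sp, seed=5)
        for chrom in m.data:
            assert np.array_equal(m.data[chrom], p.data[chrom])
            assert np.array_equal(c.data[chrom], m.data[chrom])

    def test_asymmetry_two_doubles_paternal_plateau(self, genome):
        sp = synth.StageParams("zygote", "broad", 8, (20_000, 40_000), 5.0, 0.0,
                               allelic_asymmetry=2.0)
        m, p, _ = synth.generate_stage_tracks(genome, sp, seed=5)
        for iv, level in genome.truth.planted_domains[("zygote", "maternal")]:
            ms = m.data[iv.chrom][iv.start // 500 : iv.end // 500]
            ps = p.data[iv.chrom][iv.start // 500 : iv.end // 500]
            assert np.all(ps == 2 * ms)

    def test_combined_is_allele_mean(self, genome):
        sp = synth.default_stage_params()["zygote"]
        m, p, c = synth.generate_stage_tracks(genome, sp, seed=9)
        for chrom in c.data:
            assert np.allclose(c.data[chrom], (m.data[chrom] + p.data[chrom]) / 2)


class TestAllelicFragments:
    def _tracks(self, genome, seed=5):
        sp = synth.default_stage_params()["zygote"]
        m, p, _ = synth.generate_stage_tracks(genome, sp, seed=seed)
        return m, p

    def test_clean_fragments_pass_all_filters(self, genome):
        m, p = self._tracks(genome)
        frags, _ = synth.generate_allelic_fragments(genome, m, p, 500, seed=2)
        assert all(len(f) >= 140 and f.mapq >= 30 and not f.duplicate for f in frags)

    def test_snp_calls_match_true_allele(self, genome):
        m, p = self._tracks(genome)
        frags, labels = synth.generate_allelic_fragments(genome, m, p, 2_000, seed=2)
        lookup = {(s.chrom, s.pos): (s.maternal_base, s.paternal_base) for s in genome.snps}
        for fr, lab in zip(frags, labels):
            for pos, base in fr.snp_calls:
                mat, pat = lookup[(fr.interval.chrom, pos)]
                assert base == (mat if lab == "maternal" else pat)

    def test_snp_overlap_fraction_matches_analytic(self, genome):
        # P(fragment of length L overlaps >= 1 SNP) ~ 1 - exp(-rate*L);
        # average over L ~ U(140, 500) at rate 1/1000
        m, p = self._tracks(genome)
        frags, _ = synth.generate_allelic_fragments(genome, m, p, 10_000, seed=4)
        frac = np.mean([len(f.snp_calls) > 0 for f in frags])
        lengths = np.arange(140, 501)
        expect = np.mean(1 - np.exp(-1e-3 * lengths))
        sd = math.sqrt(expect * (1 - expect) / 10_000)
        assert abs(frac - expect) <= 4 * sd

    def test_contaminant_rates_respected(self, genome):
        m, p = self._tracks(genome)
        frags, _ = synth.generate_allelic_fragments(
            genome, m, p, 2_000, seed=3,
            contaminant_fraction=0.2, low_mapq_fraction=0.2, duplicate_fraction=0.2,
        )
        short = np.mean([len(f) < 140 for f in frags])
        low = np.mean([f.mapq < 30 for f in frags])
        dup = np.mean([f.duplicate for f in frags])
        for rate in (short, low, dup):
            assert 0.1 < rate < 0.3

    def test_n_must_be_positive(self, genome):
        m, p = self._tracks(genome)
        with pytest.raises(ValueError):
            synth.generate_allelic_fragments(genome, m, p, 0)


class TestContacts:
    def test_fold_one_equals_no_loops(self, tiny_genome):
        loops = [("chr1", 3, 10, 1.0)]
        a = synth.generate_contact_matrix(tiny_genome, 10_000, loops, seed=5)
        b = synth.generate_contact_matrix(tiny_genome, 10_000, None, seed=5)
        assert np.array_equal(a.data["chr1"], b.data["chr1"])

    def test_flat_decay_gives_equal_offdiagonal_means(self, tiny_genome):
        cm = synth.generate_contact_matrix(
            tiny_genome, 10_000, None, seed=5, alpha=0.0, background_mean=50
        )
        mat = cm.data["chr1"]
        n = mat.shape[0]
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        near = mat[(d > 0) & (d <= 5)].mean()
        far = mat[d > 15].mean()
        assert abs(near - far) < 5  # both Poisson(50) means

    def test_planted_fold_ratio_in_poisson_band(self, tiny_genome):
        rng = np.random.default_rng(0)
        loops = [("chr1", int(a), int(a) + 7, 8.0) for a in rng.choice(20, 10, replace=False)]
        cm = synth.generate_contact_matrix(
            tiny_genome, 10_000, loops, seed=5, alpha=0.0, background_mean=25
        )
        mat = cm.data["chr1"]
        loop_mean = np.mean([mat[a, b] for _c, a, b, _f in loops])
        n = mat.shape[0]
        ctrl = [
            mat[i, i + 7]
            for i in range(n - 7)
            if ("chr1", i, i + 7, 8.0) not in loops
        ]
        assert 6 <= loop_mean / np.mean(ctrl) <= 10

    def test_matrix_symmetric(self, tiny_genome):
        cm = synth.generate_contact_matrix(tiny_genome, 10_000, None, seed=1)
        for c, mat in cm.data.items():
            assert np.array_equal(mat, mat.T)

    def test_anchor_outside_genome_raises(self, tiny_genome):
        with pytest.raises(ValueError, match="outside"):
            synth.generate_contact_matrix(tiny_genome, 10_000, [("chr1", 0, 10_000, 2.0)], seed=1)


class TestExpressionTables:
    def test_pcg_targets_silent_everywhere(self, genome):
        tables = synth.generate_expression_tables(genome, seed=3)
        for gid in genome.truth.gene_classes["pcg_target"]:
            assert tables["expression"].loc[gid].max() < 0.1

    def test_null_genes_in_no_set(self, genome):
        tables = synth.generate_expression_tables(genome, seed=3)
        sets = derive_all_gene_sets(
            tables["de"], tables["h3k27me3_marked"], tables["expression"]
        )
        classified = set().union(*(gs.genes for gs in sets.values()))
        null_ids = [
            g.gene_id for g in genome.genes if genome.truth.class_of(g.gene_id) is None
        ]
        assert classified.isdisjoint(null_ids)

    def test_gene_sets_recover_ledger_exactly(self, genome):
        tables = synth.generate_expression_tables(genome, seed=3)
        sets = derive_all_gene_sets(
            tables["de"], tables["h3k27me3_marked"], tables["expression"]
        )
        for name, gs in sets.items():
            assert gs.genes == frozenset(genome.truth.gene_classes[name]), name


def test_ledger_serialization_round_trip(tmp_path, tiny_genome):
    import yaml

    sp = synth.StageParams("GV", "broad", 3, (10_000, 20_000), 6.0, 0.5)
    synth.generate_stage_tracks(tiny_genome, sp, seed=1)
    path = tmp_path / "truth.yaml"
    tiny_genome.truth.save(path)
    loaded = yaml.safe_load(path.read_text())
    assert len(loaded["planted_domains"]["GV/maternal"]) == 3
    assert loaded["gene_classes"]["major_zga"] == tiny_genome.truth.gene_classes["major_zga"]
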