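"""End-to-end orchestration of the synthetic study.

One config drives the full pass: generate a genome and stage tracks,
scale every stage to the reference, call acetylation domains, cluster
the GV-to-zygote domain transitions, run the allelic, repeat, gene-set
and contact pile-up analyses, and write a machine-readable run report
plus TSV/BED/bedGraph outputs.  Every printed pipeline parameter (bin
sizes 1000/500, threshold 3, merge gap 2x bin, top 3,000 promoters,
fragment length >= 140, MAPQ >= 30, +/-2 kb promoter windows, peak
distance bounds 1 kb / 2.5 kb, contact resolution 10 kb, one shifted
control with seed 0, fold/significance cutoffs 2/0.05 and 4/0.01,
silent-gene FPKM < 0.1) is a named config key.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import allelic as allelic_mod
from . import gene_sets as gene_sets_mod
from . import hic as hic_mod
from . import io as io_mod
from . import normalization as norm_mod
from . import profiles as profiles_mod
from . import repeats as repeats_mod
from . import synth
from .domains import call_domains, domain_size_stats

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "acetydyn_out"
    # genome / tracks
    genome: synth.GenomeConfig = field(default_factory=synth.GenomeConfig)
    stages: dict = field(default_factory=synth.default_stage_params)
    track_bin_size: int = 500
    # normalization
    reference_stage: str = "ESC"
    top_n_promoters: int = 3_000
    promoter_flank: int = 2_000
    # domain calling
    domain_threshold: float = 3.0
    merge_gap_bins: int = 2  # merge gap = this many working bins
    # allelic
    n_fragments: int = 20_000
    min_fragment_length: int = 140
    min_mapq: int = 30
    allelic_bin_size: int = 1_000
    log_ratio_pseudocount: float = 0.5
    # peak classification
    promoter_peak_distance: int = 1_000
    distal_peak_distance: int = 2_500
    # contacts
    hic_resolution: int = 10_000
    hic_nshifts: int = 1
    hic_shift_seed: int = 0
    hic_pad: int = 5
    hic_alpha: float = 0.75
    hic_background_mean: float = 25.0
    loop_fold: float = 8.0
    n_loops: int = 25
    # gene sets
    minor_zga_fc: float = 2.0
    minor_zga_padj: float = 0.05
    major_fc: float = 4.0
    major_padj: float = 0.01
    min_mean_fpkm: float = 1.0
    pcg_fpkm_max: float = 0.1
    # repeats
    n_repeat_reads: int = 1_000
    repeat_read_length: int = 50

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "genome" in d and isinstance(d["genome"], dict):
            d["genome"] = synth.GenomeConfig(**d["genome"])
        if "stages" in d and isinstance(d["stages"], dict):
            stages = {}
            for name, sp in d["stages"].items():
                stages[name] = (
                    sp if isinstance(sp, synth.StageParams)
                    else synth.StageParams(stage=name, **sp)
                )
            d["stages"] = stages
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def domain_recovery(called, planted, tolerance_bp: int = 0) -> dict:
    """Precision/recall of called domains against planted intervals,
    matching boundaries within ``tolerance_bp``."""
    planted_ivs = [iv for iv, _lvl in planted]

    def matches(a, b):
        return (
            a.chrom == b.chrom
            and abs(a.start - b.start) <= tolerance_bp
            and abs(a.end - b.end) <= tolerance_bp
        )

    hit_called = sum(
        any(matches(d.interval, p) for p in planted_ivs) for d in called
    )
    hit_planted = sum(
        any(matches(d.interval, p) for d in called) for p in planted_ivs
    )
    return {
        "precision": hit_called / len(called) if called else 0.0,
        "recall": hit_planted / len(planted_ivs) if planted_ivs else 0.0,
        "n_called": len(called),
        "n_planted": len(planted_ivs),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic study; returns the run report (also
    written to ``<outdir>/report.json``)."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"seed": config.seed, "stages": {}}
    seed = config.seed

    logger.info("generating genome")
    genome = synth.generate_genome(config.genome, seed)
    io_mod.write_bed12(genome.genes, outdir / "genes.bed12")
    io_mod.write_snp_table(genome.snps, outdir / "snps.tsv")

    # --- stage tracks -----------------------------------------------------
    tracks = {}
    allele_tracks = {}
    for name, params in config.stages.items():
        m, p, c = synth.generate_stage_tracks(
            genome, params, seed, config.track_bin_size
        )
        tracks[name] = c
        allele_tracks[name] = (m, p)

    # --- cross-stage scaling ---------------------------------------------
    logger.info("computing scale factors")
    scaled, factors = norm_mod.scale_stages(
        tracks,
        genome.genes,
        reference=config.reference_stage,
        top_n=config.top_n_promoters,
        flank=config.promoter_flank,
    )
    factors.to_tsv(outdir / "scale_factors.tsv")
    report["scale_factors"] = {k: float(v) for k, v in factors.factors.items()}

    # --- domain calling ---------------------------------------------------
    domains = {}
    for name, params in config.stages.items():
        bin_size = params.call_bin_size
        doms = call_domains(
            scaled[name],
            bin_size,
            threshold=config.domain_threshold,
            merge_gap=config.merge_gap_bins * bin_size,
            stage=name,
        )
        domains[name] = doms
        io_mod.write_bed(
            [d.interval for d in doms],
            outdir / f"domains_{name}.bed",
            names=[f"{name}_{i}" for i in range(len(doms))],
            scores=[d.mean_signal for d in doms],
        )
        stats = domain_size_stats(doms)
        rec = domain_recovery(doms, genome.truth.planted_domains[(name, "both")])
        report["stages"][name] = {"domains": stats, "recovery": rec}

    # per-allele domain bases (zygote hyperacetylated paternal genome)
    allele_bases = {}
    for name, params in config.stages.items():
        f = factors.factors[name]
        per = {}
        for allele, track in zip(("maternal", "paternal"), allele_tracks[name]):
            doms = call_domains(
                track.scaled(f),
                params.call_bin_size,
                threshold=config.domain_threshold,
                merge_gap=config.merge_gap_bins * params.call_bin_size,
                stage=name,
                allele=allele,
            )
            per[allele] = domain_size_stats(doms).get("total_bases", 0.0)
        allele_bases[name] = per
    report["allelic_domain_bases"] = allele_bases

    # --- GV -> zygote domain transition clustering ------------------------
    union = domains["GV"] + domains["zygote"]
    if len(union) >= 3:
        matrix = profiles_mod.build_domain_signal_matrix(
            union, {"GV": scaled["GV"], "zygote": scaled["zygote"]}
        )
        labels, _profiles, inertia = profiles_mod.cluster_domain_transitions(
            matrix, k=3, seed=seed
        )
        report["transition_clusters"] = {
            "sizes": np.bincount(labels, minlength=3).tolist(),
            "inertia": inertia,
        }

    # --- allelic analysis (zygote) ---------------------------------------
    logger.info("allelic analysis")
    m_track, p_track = allele_tracks["zygote"]
    fragments, _labels = synth.generate_allelic_fragments(
        genome, m_track, p_track, config.n_fragments, seed
    )
    kept, removed = allelic_mod.filter_fragments(
        fragments, config.min_fragment_length, config.min_mapq
    )
    lookup = allelic_mod.snp_lookup(genome.snps)
    am, ap, assign_counts = allelic_mod.build_allelic_tracks(
        kept, lookup, genome.chromosomes, config.allelic_bin_size
    )
    planted = [iv for iv, _l in genome.truth.planted_domains[("zygote", "maternal")]]
    bias = allelic_mod.allelic_bias(
        am, ap, config.allelic_bin_size, config.log_ratio_pseudocount, regions=planted
    )
    # maternal ICRs are silenced on the maternal allele, so acetylation
    # there is paternal-biased: test maternal < paternal
    icr_regions = [iv for iv, parent in genome.icrs if parent == "maternal"]
    icr_test = allelic_mod.compare_allelic_regions(
        am, ap, icr_regions, alternative="less"
    )
    report["allelic"] = {
        "fragments_removed": removed,
        "assignment_counts": assign_counts,
        "bias_median_log2_m_over_p": bias.get("median"),
        "icr_t": icr_test["t"],
        "icr_p": icr_test["p"],
    }

    # --- repeats ----------------------------------------------------------
    logger.info("repeat quantification")
    pg = repeats_mod.build_pseudo_genome(genome.repeats, genome.sequences)
    pg.write_fasta(outdir / "repeat_pseudo_genome.fa")
    pg.annotation_gtf(outdir / "repeat_pseudo_genome.gtf")
    reads, tally = synth.generate_repeat_reads(
        genome, config.n_repeat_reads, config.repeat_read_length, seed=seed
    )
    counts = repeats_mod.quantify_repeat_reads(pg, reads)
    report["repeats"] = {
        "counts": {k: float(v) for k, v in counts.items()},
        "planted_tally": {k: int(v) for k, v in tally.items()},
        "exact_match": all(
            abs(counts.get(fam, 0) - n) < 1e-9 for fam, n in tally.items()
        ),
    }

    # --- gene sets --------------------------------------------------------
    logger.info("gene sets")
    expr = synth.generate_expression_tables(genome, seed)
    sets = gene_sets_mod.derive_all_gene_sets(
        expr["de"], expr["h3k27me3_marked"], expr["expression"]
    )
    set_report = {}
    for name, gs in sets.items():
        truth_ids = set(genome.truth.gene_classes.get(name, []))
        set_report[name] = {
            "n": len(gs),
            "matches_truth": gs.genes == frozenset(truth_ids),
        }
        gs.to_tsv(outdir / f"gene_set_{name}.tsv")
    report["gene_sets"] = set_report

    # --- promoter-enhancer pile-up ---------------------------------------
    logger.info("contact pile-up")
    zga_ids = genome.truth.gene_classes["major_zga"][: config.n_loops]
    loops, peaks = synth.plant_promoter_loops(
        genome, zga_ids, config.hic_resolution, config.loop_fold, seed=seed
    )
    contacts = synth.generate_contact_matrix(
        genome,
        config.hic_resolution,
        loops,
        seed,
        alpha=config.hic_alpha,
        background_mean=config.hic_background_mean,
    )
    pairs = [hic_mod.AnchorPair(c, a, b) for c, a, b, _f in loops]
    result = hic_mod.pileup(
        contacts, pairs, config.hic_pad, config.hic_nshifts, config.hic_shift_seed
    )
    # distance-matched control anchors at unrelated (non-ZGA) promoters
    rng = synth.substream(seed, "pileup_controls")
    non_zga = [
        g for g in genome.genes
        if genome.truth.class_of(g.gene_id) not in ("major_zga",)
    ]
    ctrl_pairs = []
    for pair in pairs:
        g = non_zga[rng.integers(len(non_zga))]
        n = -(-genome.chromosomes[g.chrom] // config.hic_resolution)
        b = g.tss // config.hic_resolution
        a = b - pair.separation if b - pair.separation >= 0 else b + pair.separation
        if 0 <= a < n:
            ctrl_pairs.append(hic_mod.AnchorPair(g.chrom, min(a, b), max(a, b)))
    ctrl_result = hic_mod.pileup(
        contacts, ctrl_pairs, config.hic_pad, config.hic_nshifts, config.hic_shift_seed
    )
    report["pileup"] = {
        "center_ratio": result.center_ratio,
        "control_center_ratio": ctrl_result.center_ratio,
        "n_pairs": result.n_pairs,
    }

    # --- three-wave summary ----------------------------------------------
    total_bases = {
        name: report["stages"][name]["domains"].get("total_bases", 0.0)
        for name in config.stages
    }
    report["three_waves"] = {
        "total_domain_bases": total_bases,
        "gv_over_mii": total_bases["GV"] / max(total_bases["MII"], 1.0),
        "zygote_over_early2c": total_bases["zygote"] / max(total_bases["early2C"], 1.0),
        "paternal_over_maternal_bases": {
            name: allele_bases[name]["paternal"] / max(allele_bases[name]["maternal"], 1.0)
            for name in config.stages
        },
    }
    report["runtime_s"] = round(time.time() - t0, 2)

    genome.truth.save(outdir / "ground_truth.yaml")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
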