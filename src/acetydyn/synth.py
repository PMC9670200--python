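"""Synthetic stage- and allele-resolved inputs with planted ground truth.

The generator emulates the structure of histone-acetylation profiling
across the mouse maternal-to-zygotic transition at desk scale: large
broad hyperacetylated domains in GV oocytes and zygotes (with the
paternal allele broader and more acetylated than the maternal), sparse
narrow domains in MII oocytes, canonical narrow peaks from the 2-cell
stage onward, allele-diagnostic SNPs carried on fragments, planted
promoter-enhancer contact enrichment, and stage-wise expression tables
with minor/major zygotic genome activation (ZGA), maternal-decay and
silent Polycomb-target classes.

Every generated feature is recorded in a :class:`GroundTruthLedger` so
downstream callers can be tested for exact recovery.  All randomness
flows through named substreams of one integer seed: regenerating any
single output never perturbs the others, and a fixed seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import ContactMatrix, FragmentRecord, Gene, GenomicInterval, SignalTrack, SnpRecord

STAGES = ["GV", "MII", "zygote", "early2C", "late2C", "morula", "ESC"]
GENE_CLASSES = [
    "zygote_minor_zga",
    "early2c_minor_zga",
    "major_zga",
    "maternal_decay",
    "pcg_target",
    "developmental_premature",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent named RNG substream derived from one master seed."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class GenomeConfig:
    """Desk-scale genome layout: 2 x 5 Mb chromosomes by default, SNPs at
    ~1/kb (emulating a hybrid cross), a small gene complement, and a few
    retrotransposon families."""

    n_chromosomes: int = 2
    chromosome_length: int = 5_000_000
    n_genes: int = 200
    gene_length_range: tuple = (5_000, 30_000)
    snp_rate: float = 1e-3
    repeat_families: dict = field(
        default_factory=lambda: {"MERVL": (30, 400, 600), "MT2": (30, 250, 450), "LINE1": (20, 600, 1200)}
    )
    repeat_divergence: float = 0.02
    n_maternal_icrs: int = 17
    n_paternal_icrs: int = 4
    icr_length: int = 3_000
    cgi_fraction: float = 0.6
    class_sizes: dict = field(
        default_factory=lambda: {
            "zygote_minor_zga": 6,
            "early2c_minor_zga": 30,
            "major_zga": 40,
            "maternal_decay": 40,
            "pcg_target": 15,
            "developmental_premature": 10,
        }
    )


@dataclass
class StageParams:
    """Acetylation-landscape parameters for one developmental stage.

    ``domain_mode`` selects the wave: ``broad`` (multi-kilobase plateaus,
    GV oocyte and zygote), ``sparse`` (few small domains, MII oocyte) or
    ``canonical`` (narrow peaks, 2-cell onward).  ``plateau_fpkm`` must
    exceed the domain-calling threshold of 3 scaled-FPKM and
    ``background_fpkm`` must stay below it.  ``allelic_asymmetry`` is the
    paternal/maternal plateau ratio and ``paternal_widen`` the fractional
    extra width added to each side of paternal domains (both model the
    hyperacetylated paternal genome in zygotes).  ``call_bin_size`` is
    the bin width the domain caller uses at this stage (1 kb for the
    broad oocyte/zygote landscapes, 500 bp for canonical-peak stages);
    planted domain boundaries are snapped to that grid.
    """

    stage: str
    domain_mode: str
    n_domains: int
    length_range: tuple
    plateau_fpkm: float = 6.0
    background_fpkm: float = 0.5
    noise_sd: float = 0.0
    allelic_asymmetry: float = 1.0
    paternal_widen: float = 0.0
    icr_effect_fpkm: float = 0.0
    call_bin_size: int = 1_000

    def __post_init__(self):
        if self.domain_mode not in ("broad", "sparse", "canonical"):
            raise ValueError(f"unknown domain_mode {self.domain_mode!r}")
        if not (self.plateau_fpkm > 3.0 > self.background_fpkm >= 0.0):
            raise ValueError("need plateau > 3 > background >= 0")
        if self.length_range[0] <= 0 or self.length_range[1] < self.length_range[0]:
            raise ValueError("invalid length range")


def default_stage_params() -> dict:
    """Per-stage defaults reproducing the three acetylation waves:
    broad domains in GV and zygote (zygote paternal allele stronger and
    wider), sparse residual domains in MII, narrow canonical peaks from
    the early 2-cell stage onward."""
    return {
        "GV": StageParams("GV", "broad", 30, (20_000, 80_000), 6.0, 0.5),
        "MII": StageParams("MII", "sparse", 6, (2_000, 6_000), 5.0, 0.2),
        "zygote": StageParams(
            "zygote", "broad", 30, (20_000, 80_000), 6.0, 0.5,
            allelic_asymmetry=1.8, paternal_widen=0.25, icr_effect_fpkm=2.0,
        ),
        "early2C": StageParams(
            "early2C", "canonical", 60, (1_000, 3_000), 8.0, 0.5, call_bin_size=500
        ),
        "late2C": StageParams(
            "late2C", "canonical", 60, (1_000, 3_000), 8.0, 0.5, call_bin_size=500
        ),
        "morula": StageParams(
            "morula", "canonical", 70, (1_000, 3_000), 8.0, 0.5, call_bin_size=500
        ),
        "ESC": StageParams(
            "ESC", "canonical", 80, (1_000, 3_000), 8.0, 0.5, call_bin_size=500
        ),
    }


# ---------------------------------------------------------------------------
# Ground truth

@dataclass
class GroundTruthLedger:
    """Record of every planted feature, for recovery testing."""

    planted_domains: dict = field(default_factory=dict)  # (stage, allele) -> [(iv, level)]
    planted_loops: list = field(default_factory=list)  # (chrom, bin_a, bin_b, fold)
    gene_classes: dict = field(default_factory=dict)  # class -> [gene_id]
    allelic_bias_regions: list = field(default_factory=list)  # (iv, log2 M/P)
    repeat_read_tally: dict = field(default_factory=dict)  # family -> count

    def class_of(self, gene_id: str) -> str | None:
        for cls, ids in self.gene_classes.items():
            if gene_id in ids:
                return cls
        return None

    def to_dict(self) -> dict:
        def iv(x):
            return {"chrom": x.chrom, "start": x.start, "end": x.end}

        return {
            "planted_domains": {
                f"{stage}/{allele}": [
                    {**iv(i), "level": float(lv)} for i, lv in doms
                ]
                for (stage, allele), doms in self.planted_domains.items()
            },
            "planted_loops": [
                {"chrom": c, "bin_a": int(a), "bin_b": int(b), "fold": float(f)}
                for c, a, b, f in self.planted_loops
            ],
            "gene_classes": {k: sorted(v) for k, v in self.gene_classes.items()},
            "allelic_bias_regions": [
                {**iv(i), "log2_ratio": float(r)} for i, r in self.allelic_bias_regions
            ],
            "repeat_read_tally": {k: int(v) for k, v in self.repeat_read_tally.items()},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class GenomeModel:
    """Synthetic genome: chromosome sequences, annotations, diagnostic
    SNPs, and the ground-truth ledger of all planted structure."""

    chromosomes: dict
    sequences: dict
    genes: list
    repeats: list  # (family, GenomicInterval) with strand on the interval
    icrs: list  # (GenomicInterval, "maternal"|"paternal")
    snps: list
    truth: GroundTruthLedger = field(default_factory=GroundTruthLedger)

    @property
    def chrom_names(self) -> list:
        return list(self.chromosomes)

    def snp_index(self) -> dict:
        """chrom -> (sorted positions array, maternal bases, paternal bases)."""
        idx = {}
        for c in self.chromosomes:
            recs = sorted((s for s in self.snps if s.chrom == c), key=lambda s: s.pos)
            idx[c] = (
                np.array([s.pos for s in recs], dtype=int),
                np.array([s.maternal_base for s in recs]),
                np.array([s.paternal_base for s in recs]),
            )
        return idx


# ---------------------------------------------------------------------------
# Placement helpers

class _Placer:
    """Rejection-samples non-overlapping intervals per chromosome, with a
    minimum gap so planted features stay unambiguous."""

    def __init__(self, chromosomes: dict, rng: np.random.Generator, min_gap: int = 0):
        self.chromosomes = chromosomes
        self.rng = rng
        self.min_gap = min_gap
        self.placed = {c: [] for c in chromosomes}

    def place(self, length: int, chrom: str | None = None, max_tries: int = 2000):
        names = list(self.chromosomes)
        for _ in range(max_tries):
            c = chrom or names[self.rng.integers(len(names))]
            size = self.chromosomes[c]
            if length >= size:
                continue
            start = int(self.rng.integers(0, size - length))
            end = start + length
            ok = all(
                end + self.min_gap <= s or start >= e + self.min_gap
                for s, e in self.placed[c]
            )
            if ok:
                self.placed[c].append((start, end))
                return c, start, end
        raise ValueError(
            f"cannot place interval of {length} bp: genome too crowded"
        )


def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.uint8)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# Genome generation

def generate_genome(config: GenomeConfig | None = None, seed: int = 0) -> GenomeModel:
    """Build a deterministic synthetic genome with genes, repeat
    instances (family consensus plus point divergence), imprinting
    control regions, hybrid-cross SNPs and planted gene classes."""
    config = config or GenomeConfig()
    chroms = {
        f"chr{i + 1}": config.chromosome_length for i in range(config.n_chromosomes)
    }

    seq_rng = substream(seed, "sequence")
    seq_codes = {c: _random_sequence(seq_rng, n) for c, n in chroms.items()}

    placer = _Placer(chroms, substream(seed, "placement"), min_gap=500)

    # repeats: per-family consensus, instances carry point divergence
    rep_rng = substream(seed, "repeats")
    repeats = []
    for family, (n_inst, lo, hi) in config.repeat_families.items():
        consensus = _random_sequence(rep_rng, hi)
        for _ in range(n_inst):
            length = int(rep_rng.integers(lo, hi + 1))
            inst = consensus[:length].copy()
            n_mut = rep_rng.binomial(length, config.repeat_divergence)
            if n_mut:
                pos = rep_rng.choice(length, size=n_mut, replace=False)
                inst[pos] = (inst[pos] + rep_rng.integers(1, 4, n_mut)) % 4
            strand = "+" if rep_rng.random() < 0.5 else "-"
            c, s, e = placer.place(length)
            if strand == "-":
                # genome carries the reverse complement of the family-oriented copy
                seq_codes[c][s:e] = (3 - inst)[::-1]
            else:
                seq_codes[c][s:e] = inst
            repeats.append((family, GenomicInterval(c, s, e, strand)))

    # genes with exon structure
    gene_rng = substream(seed, "genes")
    genes = []
    for i in range(config.n_genes):
        length = int(gene_rng.integers(*config.gene_length_range))
        c, s, e = placer.place(length)
        strand = "+" if gene_rng.random() < 0.5 else "-"
        n_ex = int(gene_rng.integers(2, 6))
        cuts = np.sort(gene_rng.choice(np.arange(1, length), 2 * n_ex - 1, replace=False))
        bounds = np.concatenate([[0], cuts, [length]])
        exons = tuple(
            (s + int(bounds[2 * k]), s + int(bounds[2 * k + 1])) for k in range(n_ex)
        )
        genes.append(
            Gene(
                f"gene{i:04d}", c, s, e, strand, exons,
                cgi=bool(gene_rng.random() < config.cgi_fraction),
            )
        )

    # imprinting control regions (positions come from the shared placer)
    icrs = []
    for parent, n in (("maternal", config.n_maternal_icrs), ("paternal", config.n_paternal_icrs)):
        for _ in range(n):
            c, s, e = placer.place(config.icr_length)
            icrs.append((GenomicInterval(c, s, e), parent))

    # SNPs: homogeneous Poisson process; maternal allele is the reference
    snp_rng = substream(seed, "snps")
    snps = []
    for c, size in chroms.items():
        n_snp = snp_rng.poisson(size * config.snp_rate)
        pos = np.sort(snp_rng.choice(size, size=n_snp, replace=False))
        for p in pos:
            ref = "ACGT"[seq_codes[c][p]]
            alt = "ACGT"[(seq_codes[c][p] + snp_rng.integers(1, 4)) % 4]
            snps.append(SnpRecord(c, int(p), ref, alt))

    # disjoint gene classes
    cls_rng = substream(seed, "classes")
    order = cls_rng.permutation(len(genes))
    truth = GroundTruthLedger()
    cursor = 0
    for cls in GENE_CLASSES:
        n = config.class_sizes.get(cls, 0)
        ids = [genes[j].gene_id for j in order[cursor : cursor + n]]
        truth.gene_classes[cls] = sorted(ids)
        cursor += n
    if cursor > len(genes):
        raise ValueError("gene class sizes exceed gene count")

    return GenomeModel(
        chromosomes=chroms,
        sequences={c: _to_str(v) for c, v in seq_codes.items()},
        genes=genes,
        repeats=repeats,
        icrs=icrs,
        snps=snps,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Stage tracks

def _snap(x: int, grid: int) -> int:
    return int(round(x / grid)) * grid


def generate_stage_tracks(
    genome: GenomeModel,
    params: StageParams,
    seed: int = 0,
    bin_size: int = 500,
) -> tuple:
    """Generate (maternal, paternal, combined) tracks for one stage.

    Domains are planted on a grid matching the stage's domain-calling
    bin size, with plateau/background levels and optional Gaussian bin
    noise (clipped at 0).  Paternal domains share maternal centers but
    may be scaled (``allelic_asymmetry``) and widened
    (``paternal_widen``).  The combined track is the allele mean.  All
    planted intervals are recorded in the ledger under
    ``(stage, maternal|paternal|both)``.
    """
    rng = substream(seed, f"tracks:{params.stage}")
    grid = params.call_bin_size
    if grid % bin_size:
        raise ValueError("track bin size must divide the stage call bin size")

    # gap wide enough that widened paternal domains never merge at calling
    margin = int(params.paternal_widen * params.length_range[1]) + 3 * grid
    placer = _Placer(genome.chromosomes, rng, min_gap=2 * margin)

    mat_doms, pat_doms = [], []
    for _ in range(params.n_domains):
        length = _snap(int(rng.integers(*params.length_range)), grid) or grid
        c, s, e = placer.place(length)
        s, e = _snap(s, grid), _snap(s, grid) + length
        if e > genome.chromosomes[c]:
            s, e = s - grid, e - grid
        mat_doms.append(GenomicInterval(c, s, e))
        w = _snap(int(params.paternal_widen * length), grid)
        ps, pe = max(0, s - w), min(genome.chromosomes[c], e + w)
        pat_doms.append(GenomicInterval(c, ps, pe))

    def build(doms, plateau, allele):
        track = SignalTrack(genome.chromosomes, bin_size, {"stage": params.stage})
        for c in track.data:
            arr = np.full(track.n_bins(c), params.background_fpkm)
            for iv in doms:
                if iv.chrom == c:
                    arr[iv.start // bin_size : iv.end // bin_size] = plateau
            if params.icr_effect_fpkm:
                # an imprinting control region is silenced on its parent
                # of origin: the opposite allele carries the acetylation.
                # The added level stays below the calling threshold so it
                # never creates an unplanted domain.
                for iv, parent in genome.icrs:
                    if iv.chrom == c and parent != allele:
                        arr[iv.start // bin_size : -(-iv.end // bin_size)] += (
                            params.icr_effect_fpkm
                        )
            if params.noise_sd > 0:
                arr = arr + rng.normal(0, params.noise_sd, arr.size)
            track.data[c] = np.clip(arr, 0.0, None)
        return track

    plat_m = params.plateau_fpkm
    plat_p = params.plateau_fpkm * params.allelic_asymmetry
    track_m = build(mat_doms, plat_m, "maternal")
    track_p = build(pat_doms, plat_p, "paternal")
    combined = SignalTrack.mean_of(track_m, track_p)
    combined.meta = {"stage": params.stage}

    truth = genome.truth
    truth.planted_domains[(params.stage, "maternal")] = [(iv, plat_m) for iv in mat_doms]
    truth.planted_domains[(params.stage, "paternal")] = [(iv, plat_p) for iv in pat_doms]
    # at zero noise the combined track clears the threshold over the wider
    # paternal interval whenever (background + paternal plateau)/2 >= 3
    both = pat_doms if (params.background_fpkm + plat_p) / 2 >= 3.0 else mat_doms
    truth.planted_domains[(params.stage, "both")] = [
        (iv, (plat_m + plat_p) / 2) for iv in both
    ]
    if params.allelic_asymmetry != 1.0:
        for iv_m, iv_p in zip(mat_doms, pat_doms):
            truth.allelic_bias_regions.append(
                (iv_m, float(np.log2(plat_m / plat_p)))
            )
    return track_m, track_p, combined


# ---------------------------------------------------------------------------
# Allelic fragments

def generate_allelic_fragments(
    genome: GenomeModel,
    track_m: SignalTrack,
    track_p: SignalTrack,
    n: int,
    seed: int = 0,
    length_range: tuple = (140, 500),
    contaminant_fraction: float = 0.0,
    low_mapq_fraction: float = 0.0,
    duplicate_fraction: float = 0.0,
) -> tuple:
    """Sample ``n`` fragments with allele-faithful SNP base calls.

    Fragment starts are drawn proportional to the true allele's track
    intensity; each fragment reports the true parental base at every SNP
    it overlaps.  Sub-140-bp contaminants, low-MAPQ fragments and
    duplicate flags are planted at the given rates.  Returns
    ``(fragments, true_allele_labels)``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = substream(seed, "fragments")
    snp_idx = genome.snp_index()
    chroms = track_m.chroms

    mass = {}
    for allele, track in (("maternal", track_m), ("paternal", track_p)):
        w = np.concatenate([track.data[c] for c in chroms]) + 1e-9
        mass[allele] = w / w.sum()
    offsets = np.cumsum([0] + [track_m.n_bins(c) for c in chroms])
    total_m = sum(track_m.data[c].sum() for c in chroms)
    total_p = sum(track_p.data[c].sum() for c in chroms)
    p_maternal = total_m / (total_m + total_p)

    fragments, labels = [], []
    for _ in range(n):
        allele = "maternal" if rng.random() < p_maternal else "paternal"
        gbin = rng.choice(mass[allele].size, p=mass[allele])
        ci = int(np.searchsorted(offsets, gbin, side="right") - 1)
        chrom = chroms[ci]
        start = int((gbin - offsets[ci]) * track_m.bin_size + rng.integers(track_m.bin_size))
        if rng.random() < contaminant_fraction:
            length = int(rng.integers(50, length_range[0]))
        else:
            length = int(rng.integers(length_range[0], length_range[1] + 1))
        end = min(start + length, genome.chromosomes[chrom])
        start = max(0, min(start, end - 50))
        pos, mat, pat = snp_idx[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        bases = mat if allele == "maternal" else pat
        calls = tuple((int(p), str(b)) for p, b in zip(pos[lo:hi], bases[lo:hi]))
        mapq = int(rng.integers(0, 30)) if rng.random() < low_mapq_fraction else 60
        dup = bool(rng.random() < duplicate_fraction)
        fragments.append(
            FragmentRecord(GenomicInterval(chrom, start, end), mapq, dup, calls)
        )
        labels.append(allele)
    return fragments, labels


# ---------------------------------------------------------------------------
# Hi-C contacts

def generate_contact_matrix(
    genome: GenomeModel,
    resolution: int = 10_000,
    loops: list | None = None,
    seed: int = 0,
    alpha: float = 0.75,
    background_mean: float = 25.0,
) -> ContactMatrix:
    """Poisson contact matrix with power-law distance decay
    ``mean(i,j) = background_mean * (1 + |i-j|)**-alpha`` and planted
    loops: pixels in ``loops = [(chrom, bin_a, bin_b, fold), ...]`` have
    their mean multiplied by ``fold`` before sampling."""
    rng = substream(seed, "contacts")
    cm = ContactMatrix(genome.chromosomes, resolution)
    loops = loops or []
    for chrom in cm.data:
        n = cm.n_bins(chrom)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        mean = background_mean * (1.0 + d) ** (-alpha)
        for c, a, b, fold in loops:
            if c != chrom:
                continue
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"loop anchor ({a},{b}) outside {chrom}")
            mean[a, b] *= fold
            mean[b, a] *= fold
        upper = np.triu(rng.poisson(mean).astype(float))
        cm.data[chrom] = upper + np.triu(upper, 1).T
    genome.truth.planted_loops.extend(loops)
    return cm


def plant_promoter_loops(
    genome: GenomeModel,
    gene_ids: list,
    resolution: int = 10_000,
    fold: float = 8.0,
    offset_bins: tuple = (5, 20),
    seed: int = 0,
) -> tuple:
    """Choose a distal anchor near each gene's TSS and return
    ``(loops, distal_peak_intervals)`` for contact-matrix planting and
    pile-up anchoring."""
    rng = substream(seed, "loops")
    by_id = {g.gene_id: g for g in genome.genes}
    loops, peaks = [], []
    for gid in gene_ids:
        g = by_id[gid]
        n = -(-genome.chromosomes[g.chrom] // resolution)
        tss_bin = g.tss // resolution
        off = int(rng.integers(*offset_bins)) * (1 if rng.random() < 0.5 else -1)
        peak_bin = tss_bin + off
        if not (0 <= peak_bin < n):
            peak_bin = tss_bin - off
        a, b = sorted((tss_bin, peak_bin))
        loops.append((g.chrom, a, b, fold))
        mid = peak_bin * resolution + resolution // 2
        peaks.append(GenomicInterval(g.chrom, max(0, mid - 250), mid + 250))
    return loops, peaks


# ---------------------------------------------------------------------------
# Expression and DE tables

EXPR_STAGES = ["MII", "zygote", "early2C", "late2C", "fourC", "morula"]
DE_CONTRASTS = [
    "drb_vs_ctrl_zygote",
    "drb_vs_ctrl_early2C",
    "late2C_vs_zygote",
    "zygote_vs_MII",
    "early2C_vs_MII",
    "late2C_vs_MII",
    "fourC_vs_MII",
]


def _padj_true(rng, cutoff):
    """Adjusted p for a planted-true contrast: log-uniform well below cutoff."""
    return float(10 ** rng.uniform(-8, np.log10(cutoff / 10)))


def generate_expression_tables(genome: GenomeModel, seed: int = 0) -> dict:
    """Synthesize per-stage FPKM and pairwise DE tables consistent with
    the planted gene classes.

    Planted-true contrasts get |log2FC| in [2.2, 5] (class cutoff 4) or
    [1.2, 3] (cutoff 2) with padj log-uniform in [1e-8, cutoff/10]; null
    genes get |log2FC| < 0.8 and padj in [0.2, 1], so the class filters
    recover the ledger exactly.  DE tables orient log2fc as condition B
    over condition A (treated over control, later stage over earlier).

    Returns ``{"expression": DataFrame(gene x stage FPKM),
    "h3k27me3_marked": {gene_id: bool}, "de": {contrast: DataFrame}}``.
    """
    rng = substream(seed, "expression")
    truth = genome.truth
    ids = [g.gene_id for g in genome.genes]
    cls_of = {gid: truth.class_of(gid) for gid in ids}

    # per-stage FPKM
    expr = pd.DataFrame(0.0, index=ids, columns=EXPR_STAGES)
    for gid in ids:
        cls = cls_of[gid]
        if cls == "pcg_target":
            expr.loc[gid] = rng.uniform(0.0, 0.05, len(EXPR_STAGES))
        elif cls == "maternal_decay":
            base = rng.uniform(10, 60)
            expr.loc[gid] = [base, base / 3, base / 8, base / 20, base / 40, base / 40]
        elif cls in ("zygote_minor_zga", "early2c_minor_zga"):
            on = 1 if cls == "zygote_minor_zga" else 2
            lvl = rng.uniform(2, 20)
            expr.loc[gid] = [0.05] * on + [lvl] * (len(EXPR_STAGES) - on)
        elif cls == "major_zga":
            lvl = rng.uniform(5, 50)
            expr.loc[gid] = [0.05, 0.2, 0.5, lvl, lvl, lvl]
        else:
            expr.loc[gid] = rng.uniform(0.5, 20)

    marked = {gid: cls_of[gid] == "pcg_target" for gid in ids}
    # a few expressed genes also carry the promoter mark: the expression
    # filter, not the mark alone, must decide membership
    nulls = [gid for gid in ids if cls_of[gid] is None]
    for gid in rng.choice(nulls, size=min(10, len(nulls)), replace=False):
        marked[gid] = True

    def table(active_cls, lfc_sign, fc_cutoff, padj_cutoff, active_subset=None):
        lfc_lo, lfc_hi = (2.2, 5.0) if fc_cutoff == 4 else (1.2, 3.0)
        rows = []
        for gid in ids:
            if cls_of[gid] == "pcg_target":
                rows.append((gid, 0.02, 0.02, 0.0, 1.0))
                continue
            active = cls_of[gid] == active_cls and (
                active_subset is None or gid in active_subset
            )
            if active:
                lfc = lfc_sign * rng.uniform(lfc_lo, lfc_hi)
                padj = _padj_true(rng, padj_cutoff)
                high = rng.uniform(2, 50)
                low = high / 2 ** abs(lfc)
                a, b = (low, high) if lfc > 0 else (high, low)
            else:
                lfc = rng.uniform(-0.8, 0.8)
                padj = rng.uniform(0.2, 1.0)
                a = rng.uniform(0.5, 20)
                b = a * 2**lfc
            rows.append((gid, a, b, lfc, padj))
        return pd.DataFrame(
            rows, columns=["gene_id", "mean_fpkm_a", "mean_fpkm_b", "log2fc", "padj"]
        )

    # maternal-decay genes fall in a random nonempty subset of the four
    # stage-vs-MII contrasts
    decay = truth.gene_classes.get("maternal_decay", [])
    decay_subsets = {c: set() for c in ("zygote_vs_MII", "early2C_vs_MII", "late2C_vs_MII", "fourC_vs_MII")}
    names = list(decay_subsets)
    for gid in decay:
        member = rng.random(4) < 0.5
        if not member.any():
            member[rng.integers(4)] = True
        for k, c in enumerate(names):
            if member[k]:
                decay_subsets[c].add(gid)

    de = {
        # DRB blocks transcription, so ZGA transcripts drop in treated (B)
        "drb_vs_ctrl_zygote": table("zygote_minor_zga", -1, 2, 0.05),
        "drb_vs_ctrl_early2C": table("early2c_minor_zga", -1, 2, 0.05),
        "late2C_vs_zygote": table("major_zga", +1, 4, 0.01),
    }
    for c in names:
        de[c] = table("maternal_decay", -1, 4, 0.01, active_subset=decay_subsets[c])

    return {"expression": expr, "h3k27me3_marked": marked, "de": de}


# ---------------------------------------------------------------------------
# Repeat-derived reads

def generate_repeat_reads(
    genome: GenomeModel,
    n: int = 1000,
    read_length: int = 50,
    background_fraction: float = 0.1,
    seed: int = 0,
) -> tuple:
    """Error-free reads from repeat instances plus random background.

    Reads are exact genome substrings inside a repeat instance (random
    strand), so they occur verbatim in the family's pseudo-chromosome.
    Returns ``(reads, tally)`` where ``tally`` counts reads per source
    family; the tally is also written to the ledger.
    """
    rng = substream(seed, "repeat_reads")
    eligible = [(fam, iv) for fam, iv in genome.repeats if len(iv) >= read_length]
    reads, tally = [], {}
    for _ in range(n):
        if rng.random() < background_fraction:
            reads.append(_to_str(_random_sequence(rng, read_length)))
            continue
        fam, iv = eligible[rng.integers(len(eligible))]
        start = int(rng.integers(iv.start, iv.end - read_length + 1))
        seq = genome.sequences[iv.chrom][start : start + read_length]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(seq)
        tally[fam] = tally.get(fam, 0) + 1
    genome.truth.repeat_read_tally = dict(tally)
    return reads, tally
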