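"""Acetylation-domain calling by bin thresholding and gap merging.

The caller rebins a scaled track to the stage's working bin size (1 kb
for the broad oocyte/zygote landscapes, 500 bp for canonical-peak
stages), takes maximal runs of bins with signal >= 3 scaled FPKM as seed
domains, and merges seeds whose end-to-end gap is at most twice the bin
size.  The merged interval's mean signal is recomputed over all its
bins, including sub-threshold gap bins, so a merged domain's mean may
dip below the threshold even though it contains qualifying bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenomicInterval, SignalTrack

DEFAULT_THRESHOLD = 3.0


@dataclass(frozen=True)
class AcetylDomain:
    interval: GenomicInterval
    stage: str = ""
    allele: str = "both"
    mean_signal: float = 0.0

    def __len__(self) -> int:
        return len(self.interval)


def call_domains(
    track: SignalTrack,
    bin_size: int,
    threshold: float = DEFAULT_THRESHOLD,
    merge_gap: int | None = None,
    stage: str = "",
    allele: str = "both",
) -> list:
    """Call domains on one track.

    merge_gap defaults to 2 x bin_size, read inclusively: seeds whose
    end-to-end distance is <= merge_gap join one domain (transitively).
    Output is sorted and non-overlapping; the last (possibly short)
    chromosome bin is clipped to the chromosome end.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if merge_gap is None:
        merge_gap = 2 * bin_size
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    work = track.rebin(bin_size)

    domains = []
    for chrom in work.chroms:
        vals = work.data[chrom]
        above = vals >= threshold
        if not above.any():
            continue
        # maximal runs of qualifying bins
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        seeds = list(zip(edges[0::2], edges[1::2]))  # bin-index half-open runs
        merged = [list(seeds[0])]
        for s, e in seeds[1:]:
            if (s - merged[-1][1]) * bin_size <= merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        size = work.chrom_sizes[chrom]
        for s, e in merged:
            start, end = s * bin_size, min(e * bin_size, size)
            domains.append(
                AcetylDomain(
                    GenomicInterval(chrom, start, end),
                    stage=stage,
                    allele=allele,
                    mean_signal=float(vals[s:e].mean()),
                )
            )
    return domains


def domain_size_stats(domains) -> dict:
    """Median and quartiles of domain sizes (bp); empty input gives an
    empty summary."""
    sizes = np.array([len(d) for d in domains], dtype=float)
    if sizes.size == 0:
        return {"n": 0}
    q1, med, q3 = np.percentile(sizes, [25, 50, 75])
    return {
        "n": int(sizes.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "total_bases": float(sizes.sum()),
    }


def annotate_domain_bases(
    domains, genes, chrom_sizes: dict, promoter_flank: int = 2_000
) -> dict:
    """Partition domain bases into promoter / exon / intron / intergenic.

    Per-base precedence is promoter > exon > intron > intergenic; the
    promoter is the +/-``promoter_flank`` window around the TSS.
    Fractions sum to 1 (all zero for empty input).
    """
    # paint precedence labels chromosome-wide: 0 intergenic, 1 intron,
    # 2 exon, 3 promoter (later paints win)
    labels = {c: np.zeros(n, dtype=np.uint8) for c, n in chrom_sizes.items()}
    for g in genes:
        labels[g.chrom][g.start : g.end] = np.maximum(labels[g.chrom][g.start : g.end], 1)
    for g in genes:
        for s, e in g.exons:
            labels[g.chrom][s:e] = np.maximum(labels[g.chrom][s:e], 2)
    for g in genes:
        s = max(0, g.tss - promoter_flank)
        e = min(chrom_sizes[g.chrom], g.tss + promoter_flank)
        labels[g.chrom][s:e] = 3

    counts = np.zeros(4, dtype=np.int64)
    for d in domains:
        iv = d.interval
        seg = labels[iv.chrom][iv.start : min(iv.end, chrom_sizes[iv.chrom])]
        counts += np.bincount(seg, minlength=4)
    total = counts.sum()
    names = ["intergenic", "intron", "exon", "promoter"]
    if total == 0:
        return {k: 0.0 for k in names}
    return {k: float(counts[i] / total) for i, k in enumerate(names)}
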