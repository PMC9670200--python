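"""Allele-specific analysis: fragment filtering, SNP-based parental
assignment, allelic coverage tracks, bias ratios and region tests.

Fragments from a hybrid cross carry diagnostic SNPs.  A fragment whose
observed bases match only the maternal genome is maternal, only the
paternal genome paternal; no informative SNP leaves it unassigned and
evidence for both alleles marks it conflicting (and it is excluded from
both allelic tracks).  The bias sign convention is fixed throughout:
positive log2 ratios mean maternal-high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import FragmentRecord, SignalTrack

MIN_FRAGMENT_LENGTH = 140
MIN_MAPQ = 30


@dataclass(frozen=True)
class AlleleCall:
    label: str  # maternal | paternal | unassigned | conflicting
    n_maternal_evidence: int
    n_paternal_evidence: int


def filter_fragments(
    fragments,
    min_len: int = MIN_FRAGMENT_LENGTH,
    min_mapq: int = MIN_MAPQ,
    drop_duplicates: bool = True,
) -> tuple:
    """Keep proper fragments: length >= 140 bp, MAPQ >= 30, and not
    flagged duplicate.  Returns ``(kept, removed_counts)`` where the
    counts report the first rule each dropped fragment failed."""
    kept, removed = [], {"short": 0, "low_mapq": 0, "duplicate": 0}
    for fr in fragments:
        if len(fr) < min_len:
            removed["short"] += 1
        elif fr.mapq < min_mapq:
            removed["low_mapq"] += 1
        elif drop_duplicates and fr.duplicate:
            removed["duplicate"] += 1
        else:
            kept.append(fr)
    return kept, removed


def assign_allele(fragment: FragmentRecord, snps: dict) -> AlleleCall:
    """Assign a fragment from its SNP base evidence.

    ``snps`` maps ``(chrom, pos) -> (maternal_base, paternal_base)``.
    Observed bases matching neither parental base are sequencing errors
    in evidence and are ignored.
    """
    m = p = 0
    chrom = fragment.interval.chrom
    for pos, base in fragment.snp_calls:
        pair = snps.get((chrom, pos))
        if pair is None:
            continue
        if base == pair[0]:
            m += 1
        elif base == pair[1]:
            p += 1
    if m and p:
        label = "conflicting"
    elif m:
        label = "maternal"
    elif p:
        label = "paternal"
    else:
        label = "unassigned"
    return AlleleCall(label, m, p)


def snp_lookup(snps) -> dict:
    """Build the ``(chrom, pos) -> (maternal, paternal)`` lookup from
    SnpRecord iterables."""
    return {(s.chrom, s.pos): (s.maternal_base, s.paternal_base) for s in snps}


def build_allelic_tracks(
    fragments, snps: dict, chrom_sizes: dict, bin_size: int = 1_000
) -> tuple:
    """Coverage tracks per allele from assigned fragments.

    Per-bin value is a fragment-coverage FPKM: overlapping fragments per
    kilobase of bin per million assigned fragments (both alleles
    pooled for the library size).  Conflicting and unassigned fragments
    contribute to neither track.  Returns ``(maternal, paternal,
    assignment_counts)``.
    """
    tracks = {
        "maternal": SignalTrack(chrom_sizes, bin_size, {"allele": "maternal"}),
        "paternal": SignalTrack(chrom_sizes, bin_size, {"allele": "paternal"}),
    }
    counts = {"maternal": 0, "paternal": 0, "unassigned": 0, "conflicting": 0}
    hits = []
    for fr in fragments:
        call = assign_allele(fr, snps)
        counts[call.label] += 1
        if call.label in ("maternal", "paternal"):
            hits.append((call.label, fr.interval))
    n_assigned = counts["maternal"] + counts["paternal"]
    if n_assigned:
        per_million = n_assigned / 1e6
        kb = bin_size / 1_000
        for allele, iv in hits:
            arr = tracks[allele].data[iv.chrom]
            first, last = iv.start // bin_size, (iv.end - 1) // bin_size
            arr[first : min(last, arr.size - 1) + 1] += 1.0 / (kb * per_million)
    return tracks["maternal"], tracks["paternal"], counts


def allelic_bias(
    track_m: SignalTrack,
    track_p: SignalTrack,
    bin_size: int = 1_000,
    pseudocount: float = 0.5,
    regions=None,
) -> dict:
    """Per-bin ``log2((M + pc) / (P + pc))`` over bins with any signal.

    Positive values are maternal-high.  ``regions`` optionally restricts
    the computation to bins overlapping the given intervals.  Returns
    the ratio array and its quartiles."""
    tm = track_m.rebin(bin_size)
    tp = track_p.rebin(bin_size)
    m = tm.genome_vector()
    p = tp.genome_vector()
    keep = (m + p) > 0
    if regions is not None:
        mask_t = SignalTrack(tm.chrom_sizes, bin_size)
        for r in regions:
            arr = mask_t.data[r.chrom]
            arr[r.start // bin_size : -(-r.end // bin_size)] = 1.0
        keep &= mask_t.genome_vector() > 0
    ratios = np.log2((m[keep] + pseudocount) / (p[keep] + pseudocount))
    if ratios.size == 0:
        return {"ratios": ratios, "n_bins": 0}
    q1, med, q3 = np.percentile(ratios, [25, 50, 75])
    return {
        "ratios": ratios,
        "n_bins": int(ratios.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
    }


def compare_allelic_regions(
    track_m: SignalTrack,
    track_p: SignalTrack,
    regions,
    alternative: str = "greater",
    paired: bool = True,
) -> dict:
    """Mean allelic signal per region plus a t-test on maternal minus
    paternal.

    ``alternative='greater'`` tests maternal > paternal.  Regions are
    matched between alleles, so the test is paired by default.  Zero
    variance of the differences leaves the t statistic undefined; the
    result is flagged ``degenerate`` with p set to NaN (or 0.5 when the
    signals are identical, the analytic one-sided null value).
    """
    regions = list(regions)
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    m = np.array([track_m.region_mean(r.chrom, r.start, r.end) for r in regions])
    p = np.array([track_p.region_mean(r.chrom, r.start, r.end) for r in regions])
    diffs = m - p
    out = {"maternal": m, "paternal": p, "n": len(regions), "degenerate": False}
    if np.allclose(diffs.std(ddof=1), 0.0):
        out["degenerate"] = True
        out["t"] = 0.0 if np.allclose(diffs, 0.0) else np.nan
        if np.allclose(diffs, 0.0):
            out["p"] = 0.5 if alternative in ("greater", "less") else 1.0
        else:
            out["p"] = np.nan
        return out
    if paired:
        res = stats.ttest_rel(m, p, alternative=alternative)
    else:
        res = stats.ttest_ind(m, p, alternative=alternative)
    out["t"], out["p"] = float(res.statistic), float(res.pvalue)
    return out
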