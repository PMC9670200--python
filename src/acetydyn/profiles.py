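"""Domain-transition clustering, track correlations, metagene/TSS
profiles, gene-density correlation and peak classification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .core import SignalTrack


@dataclass
class MetaProfile:
    """Mean positional signal across a set of anchors.

    ``bins`` are labels along the meta-coordinate (upstream flank, body
    or center, downstream flank); ``n_genes`` counts anchors actually
    averaged, ``n_skipped`` anchors dropped (e.g. genes shorter than the
    requested body resolution).
    """

    values: np.ndarray
    n_genes: int
    n_skipped: int = 0
    boundaries: tuple = ()  # indices of flank/body boundaries, if any


def build_domain_signal_matrix(
    domains, tracks: dict, flank: int = 10_000, n_bins: int = 100
) -> np.ndarray:
    """Row per domain, ``n_bins`` positional bins of each track around
    the domain center, stage layers concatenated along columns."""
    rows = []
    for d in domains:
        center = d.interval.midpoint
        layer = [
            t.region_profile(d.interval.chrom, center - flank, center + flank, n_bins)
            for t in tracks.values()
        ]
        rows.append(np.concatenate(layer))
    mat = np.asarray(rows)
    if (mat < 0).any():
        raise ValueError("negative signal in domain matrix")
    return mat


def cluster_domain_transitions(matrix: np.ndarray, k: int = 3, seed: int = 0, n_init: int = 10):
    """K-means over domain signal rows.

    Labels are renumbered by descending cluster mean of the first
    feature block so the labeling is deterministic and 0 is always the
    strongest cluster.  Returns ``(labels, cluster_means, inertia)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if matrix.shape[0] < k:
        raise ValueError(f"{matrix.shape[0]} rows < k={k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(matrix)
    means = np.array([matrix[raw == c].mean() if (raw == c).any() else -np.inf for c in range(k)])
    order = np.argsort(-means, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw]
    profiles = np.stack(
        [
            matrix[labels == c].mean(axis=0) if (labels == c).any() else np.zeros(matrix.shape[1])
            for c in range(k)
        ]
    )
    return labels, profiles, float(km.inertia_)


def correlate_tracks(
    track_a: SignalTrack,
    track_b: SignalTrack,
    bin_size: int = 5_000,
    method: str = "spearman",
    drop_double_zero: bool = True,
) -> float:
    """Genome-wide correlation of two tracks on a common bin grid.

    Bins where both tracks are zero are excluded by default (sparse
    embryo tracks are otherwise dominated by zero ties)."""
    a = track_a.rebin(bin_size).genome_vector()
    b = track_b.rebin(bin_size).genome_vector()
    if a.size != b.size:
        raise ValueError("tracks are on different genomes")
    if drop_double_zero:
        keep = (a != 0) | (b != 0)
        a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("fewer than 3 bins retained for correlation")
    if method == "spearman":
        r = stats.spearmanr(a, b).statistic
    elif method == "pearson":
        r = stats.pearsonr(a, b).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r)


def gene_density_correlation(track: SignalTrack, genes, window: int = 100_000) -> float:
    """Spearman correlation between per-window TSS counts and mean
    signal.  Constant inputs have no defined rank correlation and raise."""
    if window < track.bin_size:
        raise ValueError("window must be at least the track bin size")
    counts, signal = [], []
    for chrom in track.chroms:
        size = track.chrom_sizes[chrom]
        tss = np.array([g.tss for g in genes if g.chrom == chrom])
        for s in range(0, size, window):
            e = min(s + window, size)
            counts.append(int(((tss >= s) & (tss < e)).sum()))
            signal.append(track.region_mean(chrom, s, e))
    counts, signal = np.array(counts), np.array(signal)
    if np.all(counts == counts[0]) or np.all(signal == signal[0]):
        raise ValueError("constant input: rank correlation undefined")
    return float(stats.spearmanr(counts, signal).statistic)


def metagene_profile(
    track: SignalTrack,
    genes,
    body_bins: int = 60,
    flank: int = 10_000,
    flank_bins: int = 20,
) -> MetaProfile:
    """Scaled gene-body profile: upstream flank, TSS->TES body rescaled
    to ``body_bins``, downstream flank; minus-strand genes are reversed
    so the profile always reads TSS to TES.  Genes shorter than one
    track bin per body bin are skipped and counted."""
    if not genes:
        raise ValueError("empty gene list")
    total = np.zeros(2 * flank_bins + body_bins)
    n_used = n_skipped = 0
    for g in genes:
        if (g.end - g.start) < body_bins * track.bin_size:
            n_skipped += 1
            continue
        up = track.region_profile(g.chrom, g.start - flank, g.start, flank_bins)
        body = track.region_profile(g.chrom, g.start, g.end, body_bins)
        down = track.region_profile(g.chrom, g.end, g.end + flank, flank_bins)
        prof = np.concatenate([up, body, down])
        if g.strand == "-":
            prof = prof[::-1]
        total += prof
        n_used += 1
    if n_used == 0:
        raise ValueError("all genes skipped (shorter than body resolution)")
    return MetaProfile(
        total / n_used, n_used, n_skipped, boundaries=(flank_bins, flank_bins + body_bins)
    )


def tss_profile(track: SignalTrack, genes, flank: int = 2_000, n_bins: int = 40) -> MetaProfile:
    """TSS-centered profile over ``[TSS - flank, TSS + flank)``; minus
    strand mirrored so upstream is always on the left."""
    if not genes:
        raise ValueError("empty gene list")
    total = np.zeros(n_bins)
    for g in genes:
        prof = track.region_profile(g.chrom, g.tss - flank, g.tss + flank, n_bins)
        if g.strand == "-":
            prof = prof[::-1]
        total += prof
    return MetaProfile(total / len(genes), len(genes))


def classify_peaks_by_tss(peaks, tss_list, promoter_dist: int = 1_000, distal_dist: int = 2_500) -> dict:
    """Label peaks by midpoint distance to the nearest TSS: < 1 kb is a
    promoter peak, > 2.5 kb a distal peak, in between ``other``.
    Returns ``{peak_index: label}`` forming a partition."""
    items = tss_list.items() if isinstance(tss_list, dict) else _group_tss(tss_list)
    by_chrom = {chrom: np.sort(np.asarray(tss)) for chrom, tss in items}
    out = {}
    for i, pk in enumerate(peaks):
        tss = by_chrom.get(pk.chrom)
        if tss is None or tss.size == 0:
            out[i] = "distal"
            continue
        mid = pk.midpoint
        j = np.searchsorted(tss, mid)
        cand = tss[max(0, j - 1) : j + 1]
        d = np.abs(cand - mid).min()
        out[i] = "promoter" if d < promoter_dist else "distal" if d > distal_dist else "other"
    return out


def _group_tss(tss_list):
    grouped = {}
    for chrom, pos in tss_list:
        grouped.setdefault(chrom, []).append(pos)
    return grouped.items()


def classify_peak_response(
    peaks,
    signal_control: SignalTrack,
    signal_treated: SignalTrack,
    lost_ratio: float = 0.5,
    gain_ratio: float = 2.0,
    pseudocount: float = 0.5,
) -> dict:
    """Label each peak by its treated/control mean-signal ratio (with
    pseudocount): <= lost_ratio is ``lost``, >= gain_ratio ``enhanced``,
    else ``unaffected``."""
    if signal_control.chrom_sizes != signal_treated.chrom_sizes:
        raise ValueError("signals are on different genomes")
    out = {}
    for i, pk in enumerate(peaks):
        c = signal_control.region_mean(pk.chrom, pk.start, pk.end)
        t = signal_treated.region_mean(pk.chrom, pk.start, pk.end)
        ratio = (t + pseudocount) / (c + pseudocount)
        out[i] = "lost" if ratio <= lost_ratio else "enhanced" if ratio >= gain_ratio else "unaffected"
    return out
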