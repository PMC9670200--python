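"""Cross-stage signal scaling anchored on top promoters.

Raw FPKM coverage is not comparable across stages whose acetylation
landscapes differ in breadth, so every stage is rescaled against a
reference (embryonic stem cells by convention): rank promoters by their
signal in a +/-2 kb window around the TSS, take the median of the top
3,000 promoters in the stage and in the reference, and multiply the
stage track by reference_median / stage_median.  The reference thus has
scale factor exactly 1, and downstream analyses (notably the FPKM >= 3
domain threshold) operate on the scaled tracks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import SignalTrack

logger = logging.getLogger(__name__)

DEFAULT_PROMOTER_FLANK = 2_000
DEFAULT_TOP_N = 3_000


@dataclass
class ScaleFactorTable:
    """Per-stage multiplicative scale factors; the reference stage has
    factor 1.0 exactly."""

    reference: str
    factors: dict = field(default_factory=dict)

    def __post_init__(self):
        self.factors.setdefault(self.reference, 1.0)
        for stage, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"non-positive scale factor for {stage}")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tscale_factor\treference\n")
            for stage, f in sorted(self.factors.items()):
                fh.write(f"{stage}\t{f:.6g}\t{self.reference}\n")


def promoter_signal(
    track: SignalTrack, genes, flank: int = DEFAULT_PROMOTER_FLANK
) -> dict:
    """Per-gene mean signal over ``[TSS - flank, TSS + flank)``, clipped
    to chromosome bounds (boundary promoters average the bases that
    exist)."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    out = {}
    for g in genes:
        if g.chrom not in track.chrom_sizes:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        out[g.gene_id] = track.region_mean(g.chrom, g.tss - flank, g.tss + flank)
    return out


def _top_median(signals: dict, top_n: int) -> float:
    # descending signal, ties broken by gene id for determinism
    ranked = sorted(signals.items(), key=lambda kv: (-kv[1], kv[0]))
    return float(np.median([v for _k, v in ranked[:top_n]]))


def compute_scale_factor(
    stage_track: SignalTrack,
    reference_track: SignalTrack,
    genes,
    top_n: int = DEFAULT_TOP_N,
    flank: int = DEFAULT_PROMOTER_FLANK,
) -> float:
    """Median-of-top-``top_n``-promoters ratio, reference over stage.

    The top set is selected independently per track.  If fewer than
    ``top_n`` genes are available, all are used (with a warning).  A zero
    stage median is a degenerate track and raises.
    """
    genes = list(genes)
    if len(genes) < top_n:
        msg = f"only {len(genes)} promoters available; using all (top_n={top_n})"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    stage_med = _top_median(promoter_signal(stage_track, genes, flank), top_n)
    ref_med = _top_median(promoter_signal(reference_track, genes, flank), top_n)
    if stage_med == 0:
        raise ValueError("degenerate stage track: top-promoter median is 0")
    return ref_med / stage_med


def apply_scale(track: SignalTrack, factor: float) -> SignalTrack:
    """Multiply every bin by ``factor`` (> 0); the factor is recorded in
    track metadata."""
    return track.scaled(factor)


def scale_stages(
    tracks: dict,
    genes,
    reference: str = "ESC",
    top_n: int = DEFAULT_TOP_N,
    flank: int = DEFAULT_PROMOTER_FLANK,
) -> tuple:
    """Compute factors for every stage against ``reference`` and return
    ``(scaled_tracks, ScaleFactorTable)``."""
    if reference not in tracks:
        raise ValueError(f"reference stage {reference!r} not among tracks")
    table = ScaleFactorTable(reference)
    scaled = {}
    for stage, track in tracks.items():
        f = (
            1.0
            if stage == reference
            else compute_scale_factor(track, tracks[reference], genes, top_n, flank)
        )
        table.factors[stage] = f
        scaled[stage] = apply_scale(track, f)
    return scaled, table
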