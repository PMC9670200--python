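"""Aggregate (pile-up) Hi-C contact analysis around anchor pairs.

All same-chromosome combinations of distal elements and gene promoters
within a separation window are enumerated as anchor pairs; the observed
signal is the mean contact submatrix centered on each pair, and the
control is the same mean over randomly shifted pairs that preserve each
real pair's bin separation (so the distance-decay background divides
out without explicit expected-by-distance modeling).  The headline
statistic is the center cell of the observed/control ratio matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ContactMatrix

DEFAULT_RESOLUTION = 10_000
DEFAULT_PAD = 5
MIN_SEPARATION = 2


@dataclass(frozen=True)
class AnchorPair:
    chrom: str
    bin_a: int  # distal element
    bin_b: int  # promoter

    @property
    def separation(self) -> int:
        return abs(self.bin_a - self.bin_b)


@dataclass
class PileupResult:
    matrix: np.ndarray  # (2w+1, 2w+1) observed/control ratios (NaN = masked)
    n_pairs: int
    n_dropped: int
    pad: int

    @property
    def center_ratio(self) -> float:
        return float(self.matrix[self.pad, self.pad])


def enumerate_anchor_pairs(
    peaks,
    promoters,
    resolution: int = DEFAULT_RESOLUTION,
    min_sep: int = MIN_SEPARATION,
    max_sep: int | None = None,
) -> list:
    """All same-chromosome peak x promoter combinations with bin
    separation in ``[min_sep, max_sep]``, deduplicated at bin
    resolution."""
    if not peaks or not promoters:
        raise ValueError("peaks and promoters must both be non-empty")
    seen, pairs = set(), []
    for pk in peaks:
        a = pk.midpoint // resolution
        for pr in promoters:
            if pr.chrom != pk.chrom:
                continue
            b = pr.midpoint // resolution
            if abs(a - b) < min_sep:
                continue
            if max_sep is not None and abs(a - b) > max_sep:
                continue
            key = (pk.chrom, a, b)
            if key not in seen:
                seen.add(key)
                pairs.append(AnchorPair(pk.chrom, a, b))
    return pairs


def pileup(
    contacts: ContactMatrix,
    pairs,
    pad: int = DEFAULT_PAD,
    nshifts: int = 1,
    seed: int = 0,
) -> PileupResult:
    """Observed/control pile-up over anchor pairs.

    Observed: mean of the (2*pad+1)^2 submatrix centered at each pair's
    (bin_a, bin_b).  Control: for each real pair, ``nshifts`` uniformly
    placed pairs on the same chromosome with identical bin separation
    and in-bounds windows.  Pairs whose window leaves the matrix are
    dropped and counted.  Cells with zero control are masked (NaN).
    """
    rng = np.random.default_rng(seed)
    w = 2 * pad + 1
    obs = np.zeros((w, w))
    ctl = np.zeros((w, w))
    n_used = n_dropped = 0

    def window_ok(n, i, j):
        return pad <= i < n - pad and pad <= j < n - pad

    for pair in pairs:
        if pair.chrom not in contacts.data:
            n_dropped += 1
            continue
        mat = contacts.data[pair.chrom]
        n = mat.shape[0]
        i, j = pair.bin_a, pair.bin_b
        if not window_ok(n, i, j):
            n_dropped += 1
            continue
        obs += mat[i - pad : i + pad + 1, j - pad : j + pad + 1]
        d = j - i
        lo = pad + max(0, -d)
        hi = n - pad - max(0, d)  # exclusive bound for shifted i
        for _ in range(nshifts):
            si = int(rng.integers(lo, hi))
            sj = si + d
            ctl += mat[si - pad : si + pad + 1, sj - pad : sj + pad + 1]
        n_used += 1

    if n_used == 0:
        raise ValueError("no usable anchor pairs")
    obs /= n_used
    ctl /= n_used * nshifts
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ctl > 0, obs / ctl, np.nan)
    return PileupResult(ratio, n_used, n_dropped, pad)
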