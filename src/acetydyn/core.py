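"""Core genomic containers shared by every analysis stage.

Coordinate convention is BED-style throughout: 0-based, half-open
``[start, end)``.  Signal is carried on a fixed bin grid per chromosome
(an FPKM-like nonnegative coverage value per bin); Hi-C contacts are
dense symmetric per-chromosome matrices at a fixed resolution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GenomicInterval",
    "SnpRecord",
    "FragmentRecord",
    "Gene",
    "SignalTrack",
    "ContactMatrix",
    "natural_chrom_key",
]

_NAT_RE = re.compile(r"(\d+)")


def natural_chrom_key(name: str):
    """Sort key giving natural chromosome order (chr1 < chr2 < chr10)."""
    return tuple(int(tok) if tok.isdigit() else tok for tok in _NAT_RE.split(name))


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SnpRecord:
    """A single diagnostic SNP distinguishing the parental genomes."""

    chrom: str
    pos: int  # 0-based
    maternal_base: str
    paternal_base: str

    def __post_init__(self):
        for b in (self.maternal_base, self.paternal_base):
            if b not in "ACGT":
                raise ValueError(f"invalid base {b!r}")
        if self.maternal_base == self.paternal_base:
            raise ValueError(
                f"SNP at {self.chrom}:{self.pos} has identical parental bases"
            )


@dataclass(frozen=True)
class FragmentRecord:
    """A sequenced fragment with mapping metadata and SNP base evidence.

    ``snp_calls`` is a tuple of ``(pos, observed_base)`` for every SNP the
    fragment overlaps; positions must lie within the fragment interval.
    """

    interval: GenomicInterval
    mapq: int = 60
    duplicate: bool = False
    snp_calls: tuple = ()

    def __post_init__(self):
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        for pos, _base in self.snp_calls:
            if not (self.interval.start <= pos < self.interval.end):
                raise ValueError(
                    f"SNP call at {pos} outside fragment "
                    f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
                )

    def __len__(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class Gene:
    """Gene annotation with exon structure.

    TSS is the ``start`` coordinate for plus-strand genes and the ``end``
    coordinate for minus-strand genes (half-open convention); TES is the
    opposite end.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple = ()  # tuple of (start, end), half-open, within the gene
    cgi: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid span")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


class SignalTrack:
    """Binned nonnegative signal over a genome.

    Each chromosome holds one float array with one value per ``bin_size``
    window; the last bin may cover fewer bases.  Values are interpreted as
    a per-base density (FPKM-like), so resampling and window means are
    length-weighted.
    """

    def __init__(self, chrom_sizes: dict, bin_size: int, meta: dict | None = None):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.chrom_sizes = dict(chrom_sizes)
        self.bin_size = int(bin_size)
        self.meta = dict(meta or {})
        self.data = {
            c: np.zeros(self.n_bins(c), dtype=float) for c in self.chrom_sizes
        }

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_size)

    @property
    def chroms(self) -> list:
        return sorted(self.chrom_sizes, key=natural_chrom_key)

    def copy(self) -> "SignalTrack":
        out = SignalTrack(self.chrom_sizes, self.bin_size, self.meta)
        for c in self.data:
            out.data[c] = self.data[c].copy()
        return out

    def genome_vector(self) -> np.ndarray:
        """All bin values concatenated in natural chromosome order."""
        return np.concatenate([self.data[c] for c in self.chroms])

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted per-base mean over ``[start, end)``, clipped to
        chromosome bounds.  Returns 0.0 for an empty clipped window."""
        start = max(0, start)
        end = min(self.chrom_sizes[chrom], end)
        if end <= start:
            return 0.0
        b = self.bin_size
        first, last = start // b, (end - 1) // b
        vals = self.data[chrom][first : last + 1]
        if first == last:
            return float(vals[0])
        # bp overlap of the window with each covered bin
        w = np.full(last - first + 1, float(b))
        w[0] = (first + 1) * b - start
        w[-1] = end - last * b
        return float(np.dot(vals, w) / w.sum())

    def region_profile(self, chrom: str, start: int, end: int, n_out: int) -> np.ndarray:
        """Per-base mean signal over ``n_out`` equal sub-windows of
        ``[start, end)`` (windows outside the chromosome contribute 0)."""
        edges = np.linspace(start, end, n_out + 1)
        out = np.empty(n_out)
        for i in range(n_out):
            s, e = int(np.floor(edges[i])), int(np.ceil(edges[i + 1]))
            if e <= s:
                e = s + 1
            out[i] = self.region_mean(chrom, s, e) if e > max(0, s) else 0.0
        return out

    def rebin(self, new_bin: int) -> "SignalTrack":
        """Aggregate to a coarser grid; ``new_bin`` must be a multiple of
        the current bin size.  New values are means of constituent bins."""
        if new_bin == self.bin_size:
            return self.copy()
        if new_bin % self.bin_size:
            raise ValueError(
                f"current bin {self.bin_size} does not divide new bin {new_bin}"
            )
        k = new_bin // self.bin_size
        out = SignalTrack(self.chrom_sizes, new_bin, self.meta)
        for c, v in self.data.items():
            n_new = out.n_bins(c)
            pad = np.full(n_new * k, np.nan)
            pad[: v.size] = v
            with np.errstate(invalid="ignore"):
                out.data[c] = np.nanmean(pad.reshape(n_new, k), axis=1)
            out.data[c] = np.nan_to_num(out.data[c])
        return out

    def scaled(self, factor: float) -> "SignalTrack":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        out = self.copy()
        for c in out.data:
            out.data[c] *= factor
        out.meta["scale_factor"] = out.meta.get("scale_factor", 1.0) * factor
        return out

    @staticmethod
    def mean_of(a: "SignalTrack", b: "SignalTrack") -> "SignalTrack":
        if a.chrom_sizes != b.chrom_sizes or a.bin_size != b.bin_size:
            raise ValueError("tracks are on different grids")
        out = a.copy()
        for c in out.data:
            out.data[c] = (a.data[c] + b.data[c]) / 2.0
        return out


class ContactMatrix:
    """Symmetric per-chromosome Hi-C contact counts at fixed resolution."""

    def __init__(self, chrom_sizes: dict, resolution: int):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.chrom_sizes = dict(chrom_sizes)
        self.resolution = int(resolution)
        self.data = {}
        for c, size in self.chrom_sizes.items():
            n = -(-size // resolution)
            self.data[c] = np.zeros((n, n), dtype=float)

    def n_bins(self, chrom: str) -> int:
        return self.data[chrom].shape[0]

    def set_count(self, chrom: str, i: int, j: int, count: float) -> None:
        if count < 0:
            raise ValueError(f"negative contact count at ({chrom},{i},{j})")
        n = self.n_bins(chrom)
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"bin pair ({i},{j}) out of range for {chrom} (n={n})")
        self.data[chrom][i, j] = count
        self.data[chrom][j, i] = count

    def get_count(self, chrom: str, i: int, j: int) -> float:
        return float(self.data[chrom][i, j])
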