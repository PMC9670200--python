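"""Readers and writers for the plain-text formats the pipeline touches.

All readers emit 0-based half-open coordinates; GTF input (1-based,
closed) is converted on read.  Writers sort output by natural chromosome
order (chr1 < chr2 < chr10) then start coordinate, and every format
round-trips losslessly on its own output.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import (
    ContactMatrix,
    FragmentRecord,
    Gene,
    GenomicInterval,
    SignalTrack,
    SnpRecord,
    natural_chrom_key,
)

DE_COLUMNS = ["gene_id", "mean_fpkm_a", "mean_fpkm_b", "log2fc", "padj"]


def _interval_key(iv: GenomicInterval):
    return (natural_chrom_key(iv.chrom), iv.start, iv.end)


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path, bin_size: int, chrom_sizes: dict | None = None) -> SignalTrack:
    """Read a bedGraph into a binned :class:`SignalTrack`.

    Records need not align to the bin grid: a record's value is
    distributed to each overlapped bin weighted by overlap length over
    ``bin_size``, preserving per-base density semantics.  Unspecified
    bins are 0.  Overlapping records or negative values are errors.

    When ``chrom_sizes`` is omitted, each chromosome's size is the
    largest record end seen on it, rounded up to the bin grid.
    """
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split("\t")
            s, e, v = int(s), int(e), float(v)
            if v < 0:
                raise ValueError(f"{path}:{ln}: negative value {v}")
            if e <= s:
                raise ValueError(f"{path}:{ln}: empty interval")
            records.append((chrom, s, e, v))

    records.sort(key=lambda r: (natural_chrom_key(r[0]), r[1]))
    prev = {}
    for chrom, s, e, _v in records:
        if chrom in prev and s < prev[chrom][1]:
            ps, pe = prev[chrom]
            raise ValueError(
                f"overlapping bedGraph records on {chrom}: "
                f"[{ps},{pe}) and [{s},{e})"
            )
        prev[chrom] = (s, e)

    if chrom_sizes is None:
        chrom_sizes = {}
        for chrom, _s, e, _v in records:
            top = -(-e // bin_size) * bin_size
            chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), top)

    track = SignalTrack(chrom_sizes, bin_size)
    for chrom, s, e, v in records:
        if chrom not in track.data:
            raise ValueError(f"record on unknown chromosome {chrom}")
        arr = track.data[chrom]
        first, last = s // bin_size, (e - 1) // bin_size
        for b in range(first, min(last, arr.size - 1) + 1):
            lo, hi = max(s, b * bin_size), min(e, (b + 1) * bin_size)
            arr[b] += v * (hi - lo) / bin_size
    return track


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a track as bedGraph, merging runs of equal nonzero bins."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            arr = track.data[chrom]
            size = track.chrom_sizes[chrom]
            i = 0
            while i < arr.size:
                j = i
                while j + 1 < arr.size and arr[j + 1] == arr[i]:
                    j += 1
                if arr[i] != 0.0:
                    s = i * track.bin_size
                    e = min((j + 1) * track.bin_size, size)
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[i]:g}\n")
                i = j + 1


# ---------------------------------------------------------------------------
# BED

def write_bed(intervals, path, names=None, scores=None) -> None:
    """Write BED3 (or BED6 when names/scores given), sorted by natural
    chromosome order then start."""
    rows = list(intervals)
    order = sorted(range(len(rows)), key=lambda i: _interval_key(rows[i]))
    with open(path, "w") as fh:
        for i in order:
            iv = rows[i]
            if names is None and scores is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = names[i] if names is not None else "."
                score = f"{scores[i]:g}" if scores is not None else "0"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )


def read_bed(path) -> list:
    """Read BED3/BED6 into :class:`GenomicInterval` objects (sorted)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return sorted(out, key=_interval_key)


# ---------------------------------------------------------------------------
# Gene annotation (BED12 or minimal GTF)

def read_gene_annotation(path) -> list:
    """Read genes from BED12 or minimal GTF (detected by extension).

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    A ``cgi "true"`` GTF attribute, or a BED12 name suffixed ``|CGI``,
    marks a CpG-island promoter.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return _read_gtf(path)
    return _read_bed12(path)


def _read_bed12(path) -> list:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            cgi = name.endswith("|CGI")
            if cgi:
                name = name[: -len("|CGI")]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + offsets[i], start + offsets[i] + sizes[i])
                for i in range(n_blocks)
            )
            genes.append(Gene(name, chrom, start, end, strand, exons, cgi))
    return sorted(genes, key=lambda g: (natural_chrom_key(g.chrom), g.start))


def _read_gtf(path) -> list:
    import re

    spans, exons, strands, cgis = {}, {}, {}, {}
    chroms = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, feature, start, end, strand, attrs = (
                f[0], f[2], int(f[3]) - 1, int(f[4]), f[6], f[8],
            )
            m = re.search(r'gene_id "([^"]+)"', attrs)
            if not m:
                raise ValueError(f"GTF line without gene_id: {line!r}")
            gid = m.group(1)
            chroms[gid] = chrom
            strands[gid] = strand
            if 'cgi "true"' in attrs:
                cgis[gid] = True
            if feature == "gene":
                spans[gid] = (start, end)
            elif feature == "exon":
                exons.setdefault(gid, []).append((start, end))
    genes = []
    for gid, chrom in chroms.items():
        ex = tuple(sorted(exons.get(gid, [])))
        span = spans.get(gid) or (ex[0][0], ex[-1][1])
        genes.append(
            Gene(gid, chrom, span[0], span[1], strands[gid], ex, cgis.get(gid, False))
        )
    return sorted(genes, key=lambda g: (natural_chrom_key(g.chrom), g.start))


def write_bed12(genes, path) -> None:
    genes = sorted(genes, key=lambda g: (natural_chrom_key(g.chrom), g.start))
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons or ((g.start, g.end),)
            sizes = ",".join(str(e - s) for s, e in exons)
            offsets = ",".join(str(s - g.start) for s, e in exons)
            name = g.gene_id + ("|CGI" if g.cgi else "")
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{name}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# SNP tables

def read_snp_table(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        SnpRecord(r.chrom, int(r.pos), r.maternal_base, r.paternal_base)
        for r in df.itertuples()
    ]


def write_snp_table(snps, path) -> None:
    snps = sorted(snps, key=lambda s: (natural_chrom_key(s.chrom), s.pos))
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tmaternal_base\tpaternal_base\n")
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.maternal_base}\t{s.paternal_base}\n")


# ---------------------------------------------------------------------------
# Differential-expression tables

def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table {path} missing columns {missing}")
    if ((df.padj < 0) | (df.padj > 1)).any():
        raise ValueError("padj outside [0, 1]")
    if (df.mean_fpkm_a < 0).any() or (df.mean_fpkm_b < 0).any():
        raise ValueError("negative FPKM")
    return df[DE_COLUMNS].copy()


def write_de_table(df: pd.DataFrame, path) -> None:
    df[DE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Fragments (extended BED)

def read_fragments(path) -> list:
    """Read fragments from extended BED:
    chrom, start, end, mapq, duplicate(0/1), snp_calls ("pos:base,..." or ".")."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, s, e, mapq, dup, calls = line.split("\t")
            snp_calls = ()
            if calls != ".":
                snp_calls = tuple(
                    (int(p), b) for p, b in (x.split(":") for x in calls.split(","))
                )
            out.append(
                FragmentRecord(
                    GenomicInterval(chrom, int(s), int(e)),
                    mapq=int(mapq),
                    duplicate=bool(int(dup)),
                    snp_calls=snp_calls,
                )
            )
    return sorted(out, key=lambda fr: _interval_key(fr.interval))


def write_fragments(fragments, path) -> None:
    fragments = sorted(fragments, key=lambda fr: _interval_key(fr.interval))
    with open(path, "w") as fh:
        for fr in fragments:
            calls = (
                ",".join(f"{p}:{b}" for p, b in fr.snp_calls) if fr.snp_calls else "."
            )
            iv = fr.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fr.mapq}\t"
                f"{int(fr.duplicate)}\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# Hi-C contacts (triplet text)

def read_contacts(path, resolution: int, chrom_sizes: dict) -> ContactMatrix:
    """Read ``chrom bin_i bin_j count`` triplet lines (i <= j).

    The matrix is symmetrized on read.  Duplicate bin pairs, negative
    counts, and out-of-range bins are errors.
    """
    cm = ContactMatrix(chrom_sizes, resolution)
    seen = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, i, j, count = line.split("\t")
            i, j, count = int(i), int(j), float(count)
            if j < i:
                raise ValueError(f"{path}:{ln}: need bin_i <= bin_j")
            key = (chrom, i, j)
            if key in seen:
                raise ValueError(f"{path}:{ln}: duplicate bin pair {key}")
            seen.add(key)
            cm.set_count(chrom, i, j, count)
    return cm


def write_contacts(cm: ContactMatrix, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(cm.data, key=natural_chrom_key):
            mat = cm.data[chrom]
            n = mat.shape[0]
            for i in range(n):
                for j in range(i, n):
                    if mat[i, j] != 0.0:
                        fh.write(f"{chrom}\t{i}\t{j}\t{mat[i, j]:g}\n")
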