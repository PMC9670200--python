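"""Repeat-family pseudo-genome construction and family-level read
counting.

Each repeat family becomes one pseudo-chromosome: its genomic instances
(reverse-complemented when on the minus strand) concatenated in genomic
order with 200 Ns between consecutive instances ("between any two
sequences", so no terminal spacers).  A companion annotation treats each
pseudo-chromosome as a single gene, and a coordinate map sends every
non-spacer pseudo-genome base back to its source genome base.

Quantification here is an exact-substring placer for error-free
synthetic reads: a read counts toward a family iff it occurs on either
strand of that family's pseudo-chromosome; reads matching k > 1
families are split 1/k; reads straddling a spacer never match because N
matches no base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import GenomicInterval
from .synth import revcomp

SPACER = 200


@dataclass
class PseudoGenome:
    sequences: dict = field(default_factory=dict)  # family -> sequence
    # family -> [(source interval, offset in pseudo-chromosome)]
    coordinate_map: dict = field(default_factory=dict)

    def map_to_source(self, family: str, pseudo_pos: int):
        """Map a pseudo-chromosome position to ``(chrom, genome_pos)``;
        spacer positions map to None.

        For minus-strand instances the pseudo-chromosome carries the
        reverse complement, so pseudo offsets count from the instance's
        genomic end.
        """
        for iv, offset in self.coordinate_map[family]:
            if offset <= pseudo_pos < offset + len(iv):
                k = pseudo_pos - offset
                if iv.strand == "-":
                    return iv.chrom, iv.end - 1 - k
                return iv.chrom, iv.start + k
        return None

    def annotation_gtf(self, path) -> None:
        """Minimal GTF treating each family pseudo-chromosome as one gene
        (1-based closed coordinates on write)."""
        with open(path, "w") as fh:
            for family, seq in self.sequences.items():
                attrs = f'gene_id "{family}";'
                fh.write(f"{family}\tacetydyn\tgene\t1\t{len(seq)}\t.\t+\t.\t{attrs}\n")
                fh.write(f"{family}\tacetydyn\texon\t1\t{len(seq)}\t.\t+\t.\t{attrs}\n")

    def write_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for family, seq in sorted(self.sequences.items()):
                fh.write(f">{family}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def build_pseudo_genome(repeat_annotations, genome_sequences: dict) -> PseudoGenome:
    """Concatenate each family's instances with 200-N spacers.

    ``repeat_annotations`` is an iterable of ``(family, interval)`` with
    strand on the interval; instances are taken in genomic sort order
    and minus-strand instances are reverse-complemented.  Families with
    no instances are omitted.
    """
    from .core import natural_chrom_key

    by_family = {}
    for family, iv in repeat_annotations:
        if iv.end > len(genome_sequences[iv.chrom]):
            raise ValueError(f"repeat instance {iv} outside genome")
        by_family.setdefault(family, []).append(iv)

    pg = PseudoGenome()
    for family, instances in by_family.items():
        instances.sort(key=lambda iv: (natural_chrom_key(iv.chrom), iv.start))
        parts, cmap, offset = [], [], 0
        for i, iv in enumerate(instances):
            if i:
                parts.append("N" * SPACER)
                offset += SPACER
            seq = genome_sequences[iv.chrom][iv.start : iv.end]
            if iv.strand == "-":
                seq = revcomp(seq)
            parts.append(seq)
            cmap.append((iv, offset))
            offset += len(iv)
        pg.sequences[family] = "".join(parts)
        pg.coordinate_map[family] = cmap
    return pg


def quantify_repeat_reads(pseudo_genome: PseudoGenome, reads) -> dict:
    """Count error-free reads per family by exact substring placement.

    A read matching exactly one family (either strand) counts 1 for it;
    a read matching k families counts 1/k for each; unmatched reads are
    reported under ``_unassigned``.
    """
    counts = {family: 0.0 for family in pseudo_genome.sequences}
    counts["_unassigned"] = 0.0
    for read in reads:
        rc = revcomp(read)
        hits = [
            family
            for family, seq in pseudo_genome.sequences.items()
            if read in seq or rc in seq
        ]
        if not hits:
            counts["_unassigned"] += 1.0
        else:
            for family in hits:
                counts[family] += 1.0 / len(hits)
    return counts
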