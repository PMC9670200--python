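"""Gene-class definitions around zygotic genome activation (ZGA).

Five classes are derived from differential-expression tables and
promoter-mark/expression inputs:

* zygote / early-2-cell minor ZGA — genes significantly lower after
  transcription inhibition (DRB) than in control at that stage
  (fold change >= 2, adjusted p <= 0.05);
* major ZGA — up-regulated late 2-cell vs zygote (fold >= 4,
  padj <= 0.01);
* maternal decay — down-regulated vs MII oocyte in any of the zygote,
  early 2-cell, late 2-cell or 4-cell contrasts (fold >= 4,
  padj <= 0.01);
* PcG targets — promoter (+/-2 kb of TSS) marked by H3K27me3 with no
  expression (FPKM < 0.1) at any preimplantation stage.

Every filter additionally requires a group-mean FPKM of at least 1
(read as max of the two group means).  Fold changes are compared on the
log2 scale against exact log2(cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MIN_MEAN_FPKM = 1.0
PCG_FPKM_MAX = 0.1


@dataclass
class GeneSet:
    name: str
    genes: frozenset
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def to_tsv(self, path) -> None:
        prov = ";".join(f"{k}={v}" for k, v in sorted(self.provenance.items()))
        with open(path, "w") as fh:
            fh.write("gene_id\tset\tprovenance\n")
            for gid in sorted(self.genes):
                fh.write(f"{gid}\t{self.name}\t{prov}\n")


def de_filter(
    table: pd.DataFrame,
    fc_cutoff: float,
    padj_cutoff: float,
    min_mean_fpkm: float = DEFAULT_MIN_MEAN_FPKM,
    direction: str = "up",
) -> set:
    """Significant genes in one direction.

    ``direction='up'`` selects log2fc >= log2(fc_cutoff) (condition B
    over A), ``'down'`` selects log2fc <= -log2(fc_cutoff); both require
    padj <= padj_cutoff and max(mean_fpkm_a, mean_fpkm_b) >=
    min_mean_fpkm.
    """
    if fc_cutoff <= 0 or padj_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    if direction not in ("up", "down"):
        raise ValueError(f"unknown direction {direction!r}")
    lfc = np.log2(fc_cutoff)
    sig = table.log2fc >= lfc if direction == "up" else table.log2fc <= -lfc
    sig &= table.padj <= padj_cutoff
    sig &= np.maximum(table.mean_fpkm_a, table.mean_fpkm_b) >= min_mean_fpkm
    return set(table.loc[sig, "gene_id"])


def define_major_zga(de_late2c_vs_zygote: pd.DataFrame) -> GeneSet:
    """Genes up-regulated late 2-cell vs zygote at fold 4, padj 0.01."""
    genes = de_filter(de_late2c_vs_zygote, 4, 0.01, direction="up")
    return GeneSet(
        "major_zga", frozenset(genes),
        {"contrast": "late2C_vs_zygote", "fc": 4, "padj": 0.01, "direction": "up"},
    )


def define_maternal_decay(de_tables_vs_mii: dict) -> GeneSet:
    """Union of genes down-regulated vs MII oocyte across the supplied
    stage contrasts (zygote, early 2-cell, late 2-cell, 4-cell)."""
    genes = set()
    for name, table in de_tables_vs_mii.items():
        genes |= de_filter(table, 4, 0.01, direction="down")
    return GeneSet(
        "maternal_decay", frozenset(genes),
        {"contrasts": ",".join(sorted(de_tables_vs_mii)), "fc": 4, "padj": 0.01,
         "direction": "down"},
    )


def define_minor_zga(de_drb_vs_control: pd.DataFrame, stage: str) -> GeneSet:
    """Transcription-dependent genes at ``stage``: significantly lower
    in DRB-treated than control (fold 2, padj 0.05).  The table's log2fc
    is oriented treated over control, so these are the down genes."""
    genes = de_filter(de_drb_vs_control, 2, 0.05, direction="down")
    name = {"zygote": "zygote_minor_zga", "early2C": "early2c_minor_zga"}.get(
        stage, f"{stage}_minor_zga"
    )
    return GeneSet(
        name, frozenset(genes),
        {"contrast": f"drb_vs_ctrl_{stage}", "fc": 2, "padj": 0.05,
         "direction": "down"},
    )


def define_pcg_targets(
    promoter_h3k27me3_flags: dict,
    expression_by_stage: pd.DataFrame,
    fpkm_max: float = PCG_FPKM_MAX,
) -> GeneSet:
    """Promoter-marked genes with max FPKM across all stages strictly
    below ``fpkm_max``."""
    genes = {
        gid
        for gid, marked in promoter_h3k27me3_flags.items()
        if marked
        and gid in expression_by_stage.index
        and expression_by_stage.loc[gid].max() < fpkm_max
    }
    return GeneSet(
        "pcg_target", frozenset(genes),
        {"mark": "H3K27me3", "fpkm_max": fpkm_max, "tss_flank": 2000},
    )


def derive_all_gene_sets(
    de_tables: dict,
    promoter_h3k27me3_flags: dict,
    expression_by_stage: pd.DataFrame,
) -> dict:
    """Derive the five classes from a contrast-name-keyed table dict (as
    produced by the synthetic generator)."""
    decay_contrasts = {
        k: v for k, v in de_tables.items() if k.endswith("_vs_MII")
    }
    sets = {
        "zygote_minor_zga": define_minor_zga(de_tables["drb_vs_ctrl_zygote"], "zygote"),
        "early2c_minor_zga": define_minor_zga(
            de_tables["drb_vs_ctrl_early2C"], "early2C"
        ),
        "major_zga": define_major_zga(de_tables["late2C_vs_zygote"]),
        "maternal_decay": define_maternal_decay(decay_contrasts),
        "pcg_target": define_pcg_targets(
            promoter_h3k27me3_flags, expression_by_stage
        ),
    }
    return sets
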