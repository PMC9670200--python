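import numpy as np
import pytest

from acetydyn import synth
from acetydyn.core import Gene, SignalTrack


@pytest.fixture(scope="session")
def genome():
    """Default desk-scale genome (2 x 5 Mb), shared across tests."""
    return synth.generate_genome(synth.GenomeConfig(), seed=7)


@pytest.fixture(scope="session")
def stage_params():
    return synth.default_stage_params()


@pytest.fixture
def tiny_genome():
    """Small, fast genome for targeted tests."""
    cfg = synth.GenomeConfig(
        n_chromosomes=2,
        chromosome_length=300_000,
        n_genes=12,
        repeat_families={"FAM": (4, 100, 200)},
        n_maternal_icrs=2,
        n_paternal_icrs=1,
        class_sizes={"major_zga": 2, "pcg_target": 2},
    )
    return synth.generate_genome(cfg, seed=11)


def make_track(values_by_chrom, bin_size=1000, chrom_sizes=None):
    """SignalTrack from explicit per-chromosome bin vectors."""
    values_by_chrom = {c: np.asarray(v, dtype=float) for c, v in values_by_chrom.items()}
    if chrom_sizes is None:
        chrom_sizes = {c: len(v) * bin_size for c, v in values_by_chrom.items()}
    t = SignalTrack(chrom_sizes, bin_size)
    for c, v in values_by_chrom.items():
        t.data[c][: len(v)] = v
    return t


def make_gene(gene_id, chrom, start, end, strand="+", exons=None, cgi=False):
    return Gene(gene_id, chrom, start, end, strand, tuple(exons or ()), cgi)


@pytest.fixture
def track_factory():
    return make_track


@pytest.fixture
def gene_factory():
    return make_gene
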