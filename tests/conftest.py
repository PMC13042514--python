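import numpy as np
import pytest

import reading_m6a as rm
from reading_m6a import synthetic as syn
from reading_m6a.annotation import GenomicInterval, TranscriptModel, Transcriptome


@pytest.fixture(scope="session")
def small_sim():
    """A fully linked synthetic dataset shared by read-only tests."""
    cfg = rm.SimulationConfig(seed=42, n_genes=80)
    return cfg, syn.simulate_all(cfg)


@pytest.fixture()
def two_exon_plus():
    return TranscriptModel(
        transcript_id="tp", gene_id="gp", chrom="chr1", strand="+",
        exons=[GenomicInterval("chr1", 100, 200, "+"),
               GenomicInterval("chr1", 300, 400, "+")],
        cds_start_t=50, cds_end_t=150,
    )


@pytest.fixture()
def two_exon_minus():
    return TranscriptModel(
        transcript_id="tm", gene_id="gm", chrom="chr1", strand="-",
        exons=[GenomicInterval("chr1", 100, 200, "-"),
               GenomicInterval("chr1", 300, 400, "-")],
        cds_start_t=50, cds_end_t=150,
    )


def random_transcript(rng, chrom="chr1", max_exons=10, max_len=5000, coding=True):
    """Random toy transcript for property tests."""
    n_exons = int(rng.integers(1, max_exons + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    exons, cursor = [], int(rng.integers(0, 1000))
    budget = max_len
    for _ in range(n_exons):
        length = int(rng.integers(1, max(2, budget // n_exons)))
        exons.append(GenomicInterval(chrom, cursor, cursor + length, strand))
        budget -= length
        cursor += length + int(rng.integers(1, 500))
    total = sum(len(e) for e in exons)
    kwargs = {}
    if coding and total >= 3:
        a, b = sorted(rng.choice(total, size=2, replace=False).tolist())
        if a < b:
            kwargs = {"cds_start_t": a, "cds_end_t": b}
    return TranscriptModel(
        transcript_id="tx", gene_id="g", chrom=chrom, strand=strand,
        exons=exons, **kwargs,
    )


def exonic_bases_5to3(tx):
    """Enumeration oracle: exonic genomic positions in 5'->3' transcript order."""
    bases = [p for e in tx.exons for p in range(e.start, e.end)]
    if tx.strand == "-":
        bases = bases[::-1]
    return bases
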