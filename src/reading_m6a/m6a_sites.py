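"""Single-nucleotide m6A maps.

Two sources feed the map: GLORI-style tables carrying per-replicate
modification rates, and MeRIP peak intervals projected onto a catalogue of
known single-nucleotide sites. Both end in a DRACH-validated list of
stranded single-base records; a metagene profile summarizes their topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GenomicInterval, Transcriptome

GLORI_RATE_MIN = 0.1  # per-replicate modification-rate gate

# DRACH: D=[AGT] R=[AG] A C H=[ACT] on the site's strand (T == U)
_DRACH = ("AGT", "AG", "A", "C", "ACT")


@dataclass(frozen=True)
class M6ASite:
    chrom: str
    pos: int          # 0-based position of the methylated A
    strand: str
    rates: tuple[float, ...] = ()   # per-replicate modification rates (GLORI)
    score: float = 0.0              # peak score (MeRIP-derived)
    source: str = "GLORI"
    gene_ids: tuple[str, ...] = ()

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


@dataclass(frozen=True)
class M6APeak:
    interval: GenomicInterval
    score: float = 0.0


def filter_glori(
    sites_ctrl: list[M6ASite],
    sites_kd: list[M6ASite],
    rate_min: float = GLORI_RATE_MIN,
) -> list[M6ASite]:
    """Retain control sites confidently methylated and absent from the knockdown map.

    A site passes iff its modification rate exceeds ``rate_min`` in every
    replicate and its exact (chrom, pos, strand) was not called in the
    METTL3-knockdown cells (false-positive control).
    """
    kd_keys = {s.key for s in sites_kd}
    kept = []
    for site in sites_ctrl:
        if not site.rates:
            continue  # missing replicate data: rejected
        if all(r > rate_min for r in site.rates) and site.key not in kd_keys:
            kept.append(site)
    return kept


def drach_match(genome, site: M6ASite) -> bool:
    """True iff the strand-oriented 5-mer centered on the site's A is DRACH.

    ``genome`` is any mapping of chrom -> sequence (e.g. a pyfaidx.Fasta).
    Windows that run off the sequence ends return False.
    """
    seq = genome[site.chrom]
    if site.pos - 2 < 0 or site.pos + 3 > len(seq):
        return False
    kmer = str(seq[site.pos - 2: site.pos + 3]).upper().replace("U", "T")
    if site.strand == "-":
        kmer = _revcomp(kmer)
    return all(base in allowed for base, allowed in zip(kmer, _DRACH))


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def peaks_to_single_nt(
    peaks: list[M6APeak],
    catalogue: list[M6ASite],
    genome,
) -> list[M6ASite]:
    """Project MeRIP peaks onto known single-nucleotide sites.

    Catalogue sites overlapping any peak are retained, DRACH-filtered, and
    inherit the best (maximum) overlapping peak's score, with source MeRIP.
    """
    trees: dict[str, IntervalTree] = {}
    for pk in peaks:
        trees.setdefault(pk.interval.chrom, IntervalTree()).addi(
            pk.interval.start, pk.interval.end, pk.score
        )
    out = []
    for site in catalogue:
        tree = trees.get(site.chrom)
        if tree is None:
            continue
        hits = tree.at(site.pos)
        if not hits:
            continue
        if not drach_match(genome, site):
            continue
        out.append(M6ASite(
            chrom=site.chrom, pos=site.pos, strand=site.strand,
            rates=site.rates, score=max(h.data for h in hits),
            source="MeRIP", gene_ids=site.gene_ids,
        ))
    return out


class EmptyProfileError(ValueError):
    pass


def metagene_profile(
    sites: list[M6ASite],
    txome: Transcriptome,
    bins: int = 100,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Density of m6A sites along the metagene axis [0, 3).

    Each site is placed on the representative transcript of a gene covering it
    (coding, exonic hits only). Returns (density, bin_edges, n_unmapped);
    density integrates to 1 over mapped sites.
    """
    positions = []
    unmapped = 0
    for site in sites:
        placed = False
        for gene in txome.genes_at(site.chrom, site.pos, strand=site.strand):
            tx = txome.rep_transcript(gene)
            if not tx.is_coding:
                continue
            tpos = tx.genome_to_transcript(site.pos)
            if tpos is None:
                continue
            try:
                positions.append(tx.metagene_position(tpos))
            except ValueError:
                continue
            placed = True
            break
        if not placed:
            unmapped += 1
    if not positions:
        raise EmptyProfileError("no sites mappable to coding representative transcripts")
    counts, edges = np.histogram(positions, bins=bins, range=(0.0, 3.0), density=True)
    return counts, edges, unmapped


# -- I/O ------------------------------------------------------------------------

def read_glori_tsv(path: str) -> list[M6ASite]:
    """GLORI-style table: chrom, pos, strand, then one rate column per replicate."""
    df = pd.read_csv(path, sep="\t", comment="#")
    rate_cols = [c for c in df.columns if c.startswith("rate")]
    return [
        M6ASite(str(r["chrom"]), int(r["pos"]), str(r["strand"]),
                rates=tuple(float(r[c]) for c in rate_cols))
        for _, r in df.iterrows()
    ]


def read_peaks_bed(path: str) -> list[M6APeak]:
    """BED6 peaks; column 5 is the peak score."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return [
        M6APeak(GenomicInterval(str(r.chrom), int(r.start), int(r.end),
                                r.strand if r.strand in "+-" else "+"),
                float(r.score))
        for r in df.itertuples()
    ]


def sites_to_bed(sites: list[M6ASite], path: str) -> None:
    with open(path, "w") as fh:
        for s in sites:
            score = s.score if s.source == "MeRIP" else (min(s.rates) if s.rates else 0.0)
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\tm6A\t{score:g}\t{s.strand}\n")


def read_sites_bed(path: str, source: str = "GLORI") -> list[M6ASite]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return [
        M6ASite(str(r.chrom), int(r.start), str(r.strand),
                score=float(r.score), source=source)
        for r in df.itertuples()
    ]
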