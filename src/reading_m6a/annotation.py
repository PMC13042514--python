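"""Transcriptome data model.

Parses GTF/FASTA into lightweight transcript models, converts between genomic
and transcript coordinates, and computes transcript-topology measures
(distance to start/stop codon, metagene position) used to describe where an
m6A site falls on its host mRNA.

Coordinates are 0-based half-open (BED convention) internally; GTF's 1-based
closed intervals are converted on read.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field

import gffutils
from intervaltree import IntervalTree

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def distance_to(self, pos: int) -> int:
        """Nucleotides from ``pos`` to the nearest covered base; 0 if inside."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - (self.end - 1)
        return 0


class NoCDSError(ValueError):
    """Raised when a codon-relative measure is requested on a non-coding transcript."""


class DegenerateSegmentError(ValueError):
    """Raised when a metagene segment (5'UTR/CDS/3'UTR) is empty."""


@dataclass
class TranscriptModel:
    """Exon structure of one transcript with optional CDS boundaries.

    ``cds_start_t``/``cds_end_t`` are transcript-coordinate (5'->3') positions
    of the first base of the start and stop codon; ``None`` for non-coding.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds_start_t: int | None = None
    cds_end_t: int | None = None
    # cumulative exon lengths in genomic order, for O(log n) coordinate maps
    _starts: list[int] = field(default_factory=list, repr=False)
    _cum: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons
        self._starts = [e.start for e in exons]
        cum, total = [], 0
        for e in exons:
            cum.append(total)
            total += len(e)
        self._cum = cum
        self._length = total
        if self.cds_start_t is not None:
            if not (0 <= self.cds_start_t < self.cds_end_t < total):
                raise ValueError(
                    f"{self.transcript_id}: CDS [{self.cds_start_t}, {self.cds_end_t}] "
                    f"outside transcript of length {total}"
                )

    def __len__(self) -> int:
        return self._length

    @property
    def is_coding(self) -> bool:
        return self.cds_start_t is not None

    def genome_to_transcript(self, pos: int) -> int | None:
        """5'->3' transcript offset of genomic ``pos``, or ``None`` off-exon.

        On the minus strand, transcript position 0 maps to the largest exonic
        genomic coordinate.
        """
        if pos < 0:
            raise ValueError("genomic position must be non-negative")
        i = bisect.bisect_right(self._starts, pos) - 1
        if i < 0:
            return None
        exon = self.exons[i]
        if pos >= exon.end:
            return None
        plus_offset = self._cum[i] + (pos - exon.start)
        if self.strand == "+":
            return plus_offset
        return self._length - 1 - plus_offset

    def transcript_to_genome(self, tpos: int) -> int:
        """Genomic coordinate of transcript position ``tpos``."""
        if not 0 <= tpos < self._length:
            raise ValueError(f"transcript position {tpos} outside [0, {self._length})")
        plus_offset = tpos if self.strand == "+" else self._length - 1 - tpos
        i = bisect.bisect_right(self._cum, plus_offset) - 1
        exon = self.exons[i]
        return exon.start + (plus_offset - self._cum[i])

    def distance_to_codons(self, tpos: int) -> tuple[int, int]:
        """Absolute nt distances from ``tpos`` to the start and stop codon."""
        if not self.is_coding:
            raise NoCDSError(f"{self.transcript_id} has no CDS")
        if not 0 <= tpos < self._length:
            raise ValueError(f"transcript position {tpos} out of range")
        return abs(tpos - self.cds_start_t), abs(tpos - self.cds_end_t)

    def metagene_position(self, tpos: int) -> float:
        """Map ``tpos`` onto the metagene axis [0,3): 5'UTR->[0,1), CDS->[1,2), 3'UTR->[2,3)."""
        if not self.is_coding:
            raise NoCDSError(f"{self.transcript_id} has no CDS")
        utr5 = self.cds_start_t
        cds = self.cds_end_t - self.cds_start_t
        utr3 = self._length - self.cds_end_t
        if utr5 == 0 or cds == 0 or utr3 == 0:
            raise DegenerateSegmentError(
                f"{self.transcript_id}: empty segment (5'UTR={utr5}, CDS={cds}, 3'UTR={utr3})"
            )
        if not 0 <= tpos < self._length:
            raise ValueError(f"transcript position {tpos} out of range")
        if tpos < self.cds_start_t:
            return tpos / utr5
        if tpos < self.cds_end_t:
            return 1.0 + (tpos - self.cds_start_t) / cds
        return 2.0 + (tpos - self.cds_end_t) / utr3


class Transcriptome:
    """Transcript models keyed by id, with one representative transcript per gene.

    The representative is the longest coding transcript of the gene (longest
    of any kind if none code), ties broken lexicographically by transcript id.
    """

    def __init__(self, transcripts: dict[str, TranscriptModel]):
        self.transcripts = dict(transcripts)
        self.representative: dict[str, str] = {}
        by_gene: dict[str, list[TranscriptModel]] = {}
        for tx in self.transcripts.values():
            by_gene.setdefault(tx.gene_id, []).append(tx)
        for gene, txs in by_gene.items():
            txs.sort(key=lambda t: (not t.is_coding, -len(t), t.transcript_id))
            self.representative[gene] = txs[0].transcript_id
        self._trees: dict[str, IntervalTree] = {}
        for tx in self.transcripts.values():
            tree = self._trees.setdefault(tx.chrom, IntervalTree())
            tree.addi(tx.exons[0].start, tx.exons[-1].end, tx.transcript_id)

    def __len__(self) -> int:
        return len(self.transcripts)

    @property
    def genes(self) -> list[str]:
        return sorted(self.representative)

    def rep_transcript(self, gene_id: str) -> TranscriptModel:
        return self.transcripts[self.representative[gene_id]]

    def transcripts_at(self, chrom: str, pos: int) -> list[TranscriptModel]:
        """Transcripts whose span covers the genomic point (exonic or intronic)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((self.transcripts[iv.data] for iv in tree.at(pos)),
                      key=lambda t: t.transcript_id)

    def genes_at(self, chrom: str, pos: int, strand: str | None = None) -> list[str]:
        hits = {t.gene_id for t in self.transcripts_at(chrom, pos)
                if strand is None or t.strand == strand}
        return sorted(hits)

    # -- serialization (the `annot build` index) --------------------------------

    def to_json(self, path: str) -> None:
        payload = {
            "transcripts": [
                {
                    "transcript_id": t.transcript_id,
                    "gene_id": t.gene_id,
                    "chrom": t.chrom,
                    "strand": t.strand,
                    "exons": [[e.start, e.end] for e in t.exons],
                    "cds_start_t": t.cds_start_t,
                    "cds_end_t": t.cds_end_t,
                }
                for t in self.transcripts.values()
            ]
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "Transcriptome":
        with open(path) as fh:
            payload = json.load(fh)
        txs = {}
        for rec in payload["transcripts"]:
            txs[rec["transcript_id"]] = TranscriptModel(
                transcript_id=rec["transcript_id"],
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=[GenomicInterval(rec["chrom"], s, e, rec["strand"])
                       for s, e in rec["exons"]],
                cds_start_t=rec["cds_start_t"],
                cds_end_t=rec["cds_end_t"],
            )
        return cls(txs)


def _cds_transcript_bounds(tx: TranscriptModel, cds_intervals: list[tuple[int, int]]) -> tuple[int, int]:
    """Transcript-coordinate first base of start codon and of stop codon."""
    tpos = []
    for start, end in cds_intervals:
        for g in (start, end - 1):
            t = tx.genome_to_transcript(g)
            if t is not None:
                tpos.append(t)
    lo, hi = min(tpos), max(tpos)
    # GTF CDS excludes the stop codon: its first base is one past the last CDS base
    return lo, hi + 1


def load_transcriptome(gtf_path: str) -> Transcriptome:
    """Build a :class:`Transcriptome` from an Ensembl-dialect GTF.

    Requires ``gene_id`` and ``transcript_id`` attributes on exon/CDS features.
    GTF 1-based closed coordinates become 0-based half-open.
    """
    db = gffutils.create_db(
        gtf_path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    exons: dict[str, dict] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        start, end = feat.start - 1, feat.end  # to 0-based half-open
        if feat.featuretype == "exon":
            rec = exons.setdefault(
                tid, {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "ivals": []}
            )
            rec["ivals"].append((start, end))
        else:
            cds.setdefault(tid, []).append((start, end))

    transcripts = {}
    for tid, rec in exons.items():
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=[GenomicInterval(rec["chrom"], s, e, rec["strand"]) for s, e in rec["ivals"]],
        )
        if tid in cds:
            lo, hi = _cds_transcript_bounds(tx, cds[tid])
            tx = TranscriptModel(
                transcript_id=tid, gene_id=rec["gene_id"], chrom=rec["chrom"],
                strand=rec["strand"], exons=tx.exons, cds_start_t=lo, cds_end_t=hi,
            )
        transcripts[tid] = tx
    return Transcriptome(transcripts)
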