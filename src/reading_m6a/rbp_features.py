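"""RBP-binding-context feature encoding.

Each m6A-positive gene (or exon event) is described by eleven feature sets:

1.  score of the RBP binding site nearest an m6A site on the genome
2.  the same in transcript coordinates
3.  minimum RBP-to-m6A distance over the gene's sites, genome
4.  minimum distance, transcript
5.  maximum distance, genome
6.  maximum distance, transcript
7.  site-to-gene topology (distance to start/stop codon, metagene position)
8.  per-tissue expression of the gene (gene level only)
9.  gene dependency score (gene level only)
10. nearest transcript distance from an m6A site to each 6-mer
11. maximum count of each k-mer within +/-100 nt of an m6A site

Exon-level vectors anchor every RBP feature on the single m6A site closest to
the exon boundary (within 10 kb), take no min/max over sites, and omit sets
8-9. Missing values (no binding site, gene absent from a table) are NaN so
tree models treat them as missing rather than as distance zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GenomicInterval, TranscriptModel, Transcriptome
from .m6a_sites import M6ASite

EXON_M6A_WINDOW = 10_000  # nt: exon-boundary to m6A search window
FLANK = 100               # nt each side for k-mer counting (set 11)

MISSING = math.nan


@dataclass(frozen=True)
class RBPBindingSite:
    rbp: str
    interval: GenomicInterval
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("binding score must be non-negative")


class RBPTrack:
    """All binding sites of one RBP, indexed for nearest-site queries."""

    def __init__(self, rbp: str, sites: list[RBPBindingSite]):
        self.rbp = rbp
        self.sites = sites
        self._by_chrom: dict[str, list[RBPBindingSite]] = {}
        for s in sites:
            self._by_chrom.setdefault(s.interval.chrom, []).append(s)
        # flat arrays per chromosome for vectorized distance queries
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ss in self._by_chrom.items():
            self._arrays[chrom] = (
                np.array([s.interval.start for s in ss]),
                np.array([s.interval.end for s in ss]),
                np.array([s.score for s in ss]),
            )

    def nearest_genome(self, chrom: str, pos: int) -> tuple[float, float]:
        """(distance, score) of the nearest site on the genome; (nan, nan) if none.

        Ties on distance break toward the higher score, then the leftmost start.
        """
        arrs = self._arrays.get(chrom)
        if arrs is None:
            return MISSING, MISSING
        starts, ends, scores = arrs
        d = np.maximum(0, np.maximum(starts - pos, pos - (ends - 1)))
        idx = np.lexsort((starts, -scores, d))[0]
        return float(d[idx]), float(scores[idx])

    def nearest_transcript(self, tx: TranscriptModel, anchor_tpos: int) -> tuple[float, float]:
        """(distance, score) of the nearest site in transcript coordinates.

        A site qualifies if any of its bases is exonic on ``tx``; its covered
        transcript positions are the converted exonic bases, and the distance
        is 0 inside, else nt to the nearest covered transcript base.
        """
        arrs = self._arrays.get(tx.chrom)
        if arrs is None:
            return MISSING, MISSING
        starts, ends, _ = arrs
        span_lo, span_hi = tx.exons[0].start, tx.exons[-1].end
        candidates = np.nonzero((ends > span_lo) & (starts < span_hi))[0]
        best = None
        sites = self._by_chrom[tx.chrom]
        for i in candidates:
            s = sites[i]
            span = _transcript_span(tx, s.interval)
            if span is None:
                continue
            lo, hi = span
            if lo <= anchor_tpos <= hi:
                d = 0
            else:
                d = lo - anchor_tpos if anchor_tpos < lo else anchor_tpos - hi
            cand = (d, -s.score, s.interval.start)
            if best is None or cand < best[0]:
                best = (cand, s)
        if best is None:
            return MISSING, MISSING
        return float(best[0][0]), best[1].score


def _transcript_span(tx: TranscriptModel, ival: GenomicInterval) -> tuple[int, int] | None:
    """Min/max transcript position of the interval's exonic bases, or None."""
    tpos = []
    for exon in tx.exons:
        lo = max(exon.start, ival.start)
        hi = min(exon.end, ival.end)
        if lo < hi:
            for g in (lo, hi - 1):
                t = tx.genome_to_transcript(g)
                if t is not None:
                    tpos.append(t)
    if not tpos:
        return None
    return min(tpos), max(tpos)


def nearest_rbp(
    track: RBPTrack,
    anchor: M6ASite,
    space: str,
    txome: Transcriptome | None = None,
) -> tuple[float, float]:
    """Nearest-site (distance, score) for one anchor, in genome or transcript space."""
    if space == "genome":
        return track.nearest_genome(anchor.chrom, anchor.pos)
    if space == "transcript":
        if txome is None:
            raise ValueError("transcript space requires a transcriptome")
        genes = [g for g in (anchor.gene_ids or txome.genes_at(anchor.chrom, anchor.pos,
                                                               strand=anchor.strand))]
        for gene in genes:
            tx = txome.rep_transcript(gene)
            tpos = tx.genome_to_transcript(anchor.pos)
            if tpos is not None:
                return track.nearest_transcript(tx, tpos)
        return MISSING, MISSING
    raise ValueError(f"unknown space {space!r}")


def m6a_rbp_distance_summary(
    gene_sites: list[M6ASite],
    track: RBPTrack,
    space: str,
    txome: Transcriptome | None = None,
) -> tuple[float, float]:
    """(min, max) over the gene's m6A sites of each site's nearest-RBP distance."""
    dists = []
    for site in gene_sites:
        d, _ = nearest_rbp(track, site, space, txome)
        if not math.isnan(d):
            dists.append(d)
    if not dists:
        return MISSING, MISSING
    return min(dists), max(dists)


def kmer_features(
    tx_seq: str,
    site_tpos: list[int],
    vocabulary: list[str],
    flank: int = FLANK,
) -> dict[str, tuple[float, float]]:
    """Per-k-mer (nearest transcript distance, max flank count) over the gene's sites.

    Distance is |site tpos - occurrence start| minimized over occurrences
    (overlapping scan) and then over sites; count is the number of occurrence
    starts within +/-``flank`` nt of a site, maximized over sites, with the
    window truncated at transcript ends.
    """
    seq = tx_seq.upper().replace("U", "T")
    out = {}
    for kmer in vocabulary:
        km = kmer.upper().replace("U", "T")
        occs = _find_all(seq, km)
        if not occs:
            out[kmer] = (MISSING, 0.0)
            continue
        occ_arr = np.asarray(occs)
        best_d = min(int(np.abs(occ_arr - t).min()) for t in site_tpos)
        best_c = max(int(((occ_arr >= t - flank) & (occ_arr <= t + flank)).sum())
                     for t in site_tpos)
        out[kmer] = (float(best_d), float(best_c))
    return out


def _find_all(seq: str, kmer: str) -> list[int]:
    occs, i = [], seq.find(kmer)
    while i != -1:
        occs.append(i)
        i = seq.find(kmer, i + 1)
    return occs


def drach_vocabulary() -> list[str]:
    """The 18 DRACH 5-mers, the default k-mer vocabulary."""
    return sorted(d + r + "AC" + h for d in "AGT" for r in "AG" for h in "ACT")


# -- assembly -------------------------------------------------------------------

RBP_FEATURES_GENE = ("score_g", "score_t", "mind_g", "mind_t", "maxd_g", "maxd_t")
RBP_FEATURES_EXON = ("score_g", "score_t", "dist_g", "dist_t")
GENE_ONLY_SETS = ("expression", "dependency")


def assemble_features(
    units: list[str],
    m6a_by_gene: dict[str, list[M6ASite]],
    tracks: list[RBPTrack],
    txome: Transcriptome,
    tx_sequences: dict[str, str],
    expression: pd.DataFrame | None = None,
    dependency: pd.Series | None = None,
    level: str = "gene",
    exon_events: dict[str, "object"] | None = None,
    vocabulary: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the full feature matrix for gene- or exon-level units.

    Gene level requires >=1 retained m6A site per gene; units without one are
    excluded. Exon level requires an m6A site within 10 kb of either exon
    boundary; the closest such site (ties toward the 5' boundary) anchors all
    RBP features, and gene-level-only sets (expression, dependency) are
    omitted. ``tx_sequences`` maps transcript id -> spliced sequence.
    """
    vocab = vocabulary if vocabulary is not None else drach_vocabulary()
    if level == "gene":
        rows = [_encode_gene(g, m6a_by_gene.get(g, []), tracks, txome, tx_sequences,
                             expression, dependency, vocab)
                for g in units]
    elif level == "exon":
        if exon_events is None:
            raise ValueError("exon level requires exon_events")
        rows = [_encode_exon(u, exon_events[u], m6a_by_gene, tracks, txome,
                             tx_sequences, vocab)
                for u in units]
    else:
        raise ValueError(f"unknown level {level!r}")
    rows = [r for r in rows if r is not None]
    df = pd.DataFrame(rows).set_index("unit_id") if rows else pd.DataFrame()
    return df


def _topology(tx: TranscriptModel, tpos_list: list[int]) -> dict[str, float]:
    d_start, d_stop, meta = [], [], []
    for t in tpos_list:
        try:
            ds, de = tx.distance_to_codons(t)
        except ValueError:
            continue
        d_start.append(ds)
        d_stop.append(de)
        try:
            meta.append(tx.metagene_position(t))
        except ValueError:
            pass
    return {
        "topo:min_dist_start": float(min(d_start)) if d_start else MISSING,
        "topo:min_dist_stop": float(min(d_stop)) if d_stop else MISSING,
        "topo:mean_metagene": float(np.mean(meta)) if meta else MISSING,
        "topo:n_sites": float(len(tpos_list)),
    }


def _encode_gene(gene, sites, tracks, txome, tx_sequences, expression, dependency, vocab):
    if not sites or gene not in txome.representative:
        return None
    tx = txome.rep_transcript(gene)
    row: dict[str, float] = {"unit_id": gene}
    for track in tracks:
        for space, tag in (("genome", "g"), ("transcript", "t")):
            per_site = [nearest_rbp(track, s, space, txome) for s in sites]
            per_site = [(d, sc) for d, sc in per_site if not math.isnan(d)]
            if per_site:
                dmin, smin = min(per_site, key=lambda p: (p[0], -p[1]))
                dmax = max(d for d, _ in per_site)
            else:
                dmin = smin = dmax = MISSING
            row[f"rbp:{track.rbp}:score_{tag}"] = smin
            row[f"rbp:{track.rbp}:mind_{tag}"] = dmin
            row[f"rbp:{track.rbp}:maxd_{tag}"] = dmax
    tpos = [t for t in (tx.genome_to_transcript(s.pos) for s in sites) if t is not None]
    if not tpos:
        return None
    row.update(_topology(tx, tpos))
    if expression is not None:
        for tissue in expression.columns:
            row[f"expression:{tissue}"] = (
                float(expression.at[gene, tissue]) if gene in expression.index else MISSING
            )
    if dependency is not None:
        row["dependency:score"] = (
            float(dependency[gene]) if gene in dependency.index else MISSING
        )
    seq = tx_sequences.get(tx.transcript_id, "")
    for kmer, (d, c) in kmer_features(seq, tpos, vocab).items():
        row[f"kmer_dist:{kmer}"] = d
        row[f"kmer_count:{kmer}"] = c
    return row


def _closest_site_to_exon(exon: GenomicInterval, sites: list[M6ASite],
                          window: int = EXON_M6A_WINDOW) -> M6ASite | None:
    """Closest m6A site to the nearer exon boundary; ties toward the 5' boundary."""
    five_prime = exon.start if exon.strand == "+" else exon.end - 1
    best = None
    for s in sites:
        if s.chrom != exon.chrom:
            continue
        d = min(abs(s.pos - exon.start), abs(s.pos - (exon.end - 1)))
        if d > window:
            continue
        cand = (d, abs(s.pos - five_prime), s.pos)
        if best is None or cand < best[0]:
            best = (cand, s)
    return best[1] if best else None


def _encode_exon(event_id, event, m6a_by_gene, tracks, txome, tx_sequences, vocab):
    gene = event.gene_id
    sites = m6a_by_gene.get(gene, [])
    anchor = _closest_site_to_exon(event.exon, sites)
    if anchor is None or gene not in txome.representative:
        return None
    tx = txome.rep_transcript(gene)
    tpos = tx.genome_to_transcript(anchor.pos)
    if tpos is None:
        return None
    row: dict[str, float] = {"unit_id": event_id}
    for track in tracks:
        dg, sg = nearest_rbp(track, anchor, "genome", txome)
        dt, st_ = nearest_rbp(track, anchor, "transcript", txome)
        row[f"rbp:{track.rbp}:score_g"] = sg
        row[f"rbp:{track.rbp}:score_t"] = st_
        row[f"rbp:{track.rbp}:dist_g"] = dg
        row[f"rbp:{track.rbp}:dist_t"] = dt
    row.update(_topology(tx, [tpos]))
    seq = tx_sequences.get(tx.transcript_id, "")
    for kmer, (d, c) in kmer_features(seq, [tpos], vocab).items():
        row[f"kmer_dist:{kmer}"] = d
        row[f"kmer_count:{kmer}"] = c
    return row


def feature_sets(columns) -> dict[str, list[str]]:
    """Partition feature columns into the eleven named sets (present ones only)."""
    sets: dict[str, list[str]] = {}
    mapping = {
        "score_g": "1_rbp_score_genome", "score_t": "2_rbp_score_transcript",
        "mind_g": "3_min_dist_genome", "mind_t": "4_min_dist_transcript",
        "maxd_g": "5_max_dist_genome", "maxd_t": "6_max_dist_transcript",
        "dist_g": "3_min_dist_genome", "dist_t": "4_min_dist_transcript",
    }
    for col in columns:
        if col.startswith("rbp:"):
            name = mapping[col.rsplit(":", 1)[1]]
        elif col.startswith("topo:"):
            name = "7_topology"
        elif col.startswith("expression:"):
            name = "8_expression"
        elif col.startswith("dependency:"):
            name = "9_dependency"
        elif col.startswith("kmer_dist:"):
            name = "10_kmer_distance"
        elif col.startswith("kmer_count:"):
            name = "11_kmer_flank_count"
        else:
            raise ValueError(f"unrecognized feature column {col!r}")
        sets.setdefault(name, []).append(col)
    return sets


def variability_metrics(
    distances: dict[str, dict[str, float]],
    log2fc: dict[str, dict[str, float]],
) -> pd.DataFrame:
    """Per-gene cross-cell-type variability.

    ``distances``/``log2fc`` map gene -> {cell type -> value}. CV of the m6A-to-
    reader distances uses the sample SD (ddof=1) over the mean; readout
    variability is the SD of log2 fold changes. Genes observed in fewer than
    two cell types, or with mean distance 0, get NaN.
    """
    rows = []
    for gene in sorted(set(distances) | set(log2fc)):
        dv = np.array(list(distances.get(gene, {}).values()), dtype=float)
        fv = np.array(list(log2fc.get(gene, {}).values()), dtype=float)
        cv = MISSING
        if dv.size >= 2 and dv.mean() != 0:
            cv = float(dv.std(ddof=1) / dv.mean())
        sd = float(fv.std(ddof=1)) if fv.size >= 2 else MISSING
        rows.append({"gene_id": gene, "cv_distance": cv, "sd_log2fc": sd})
    return pd.DataFrame(rows).set_index("gene_id")


def read_rbp_tracks_bed(path: str) -> list[RBPTrack]:
    """BED6 where the name column carries the RBP identity."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"])
    by_rbp: dict[str, list[RBPBindingSite]] = {}
    for r in df.itertuples():
        site = RBPBindingSite(
            str(r.name),
            GenomicInterval(str(r.chrom), int(r.start), int(r.end),
                            r.strand if r.strand in "+-" else "+"),
            float(r.score),
        )
        by_rbp.setdefault(site.rbp, []).append(site)
    return [RBPTrack(rbp, sites) for rbp, sites in sorted(by_rbp.items())]
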