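"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the count-level inputs the pipeline consumes: a toy
genome and GTF with multi-exon coding transcripts, DRACH-anchored m6A sites
near stop codons, actinomycin-D decay time courses with ERCC spike-in rows
and planted half-life changes, RPF/RNA count pairs with planted TE shifts,
cassette-exon junction tables with planted Psi shifts, RBP binding tracks
whose score near m6A sites is coupled to planted readout labels, GLORI-style
site tables, and HyperTRIBE editing matrices with deliberate filter-boundary
cases. All outputs are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomicInterval, TranscriptModel, Transcriptome
from .m6a_sites import M6ASite
from .readouts import CountMatrix, ExonEvent, SampleInfo
from .rbp_features import RBPBindingSite, RBPTrack
from .tribe import EditingSiteRecord

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiments.

    Defaults mirror the emulated study design: two biological replicates,
    time points 0/1/3/6 h with an ultra-deep 0 h library, half-lives of a few
    hours, a 1.5-fold half-life call threshold (planted changes are 2-fold so
    true effects sit clearly past it), and twenty RBP tracks of which one is
    the planted reader.
    """

    seed: int
    n_genes: int = 200
    # gene geometry
    exon_range: tuple[int, int] = (2, 5)
    exon_len_range: tuple[int, int] = (150, 400)
    intron_len_range: tuple[int, int] = (200, 800)
    gap_range: tuple[int, int] = (500, 2000)
    utr5_range: tuple[int, int] = (80, 250)
    utr3_range: tuple[int, int] = (150, 500)
    # m6A placement
    p_m6a_gene: float = 0.9
    m6a_per_gene_mean: float = 1.5
    m6a_stop_sd: float = 80.0       # nt spread of sites around the stop codon
    # decay experiment
    depth: float = 200.0            # mean 0-effect counts per gene per replicate
    n_replicates: int = 2
    times_h: tuple[float, ...] = (0.0, 1.0, 3.0, 6.0)
    k_log_mean: float = math.log(0.3)   # control rates ~ lognormal, half-life ~3 h
    k_log_sd: float = 0.3
    gene_factor_sd: float = 0.3         # lognormal spread of per-gene abundance
    planted_hl_fraction: float = 0.2
    planted_hl_fold: float = 2.0
    deep_t0_scale: float = 4.0      # ultra-deep 0 h library factor
    n_ercc: int = 20
    ercc_fraction: float = 0.05     # ERCC share of the 0 h mRNA pool
    # TE experiment
    te_replicates: int = 2
    planted_te_fraction: float = 0.2
    planted_te_fold: float = 4.0
    # splicing experiment
    junction_depth: int = 200
    planted_psi_fraction: float = 0.2
    planted_psi_shift: float = 0.4
    inclusion_eff_len: float = 2.0
    skipping_eff_len: float = 1.0
    # RBP tracks / model labels
    n_rbp: int = 20
    reader_rbp: str = "RBP00"
    p_signal: float = 0.9
    reader_offset_range: tuple[int, int] = (10, 150)
    reader_site_len: int = 20
    reader_score: tuple[float, float] = (8.0, 1.2)       # near-m6A score, positive genes
    background_score: tuple[float, float] = (2.5, 1.2)   # near-m6A score, negative genes
    p_background_site: float = 0.5
    n_tissues: int = 5
    # editing data
    n_true_edit_sites: int = 30
    n_false_edit_sites: int = 30
    edit_coverage_mean: float = 80.0


@dataclass
class GroundTruth:
    k_control: dict[str, float] = field(default_factory=dict)
    k_kd: dict[str, float] = field(default_factory=dict)
    hl_label: dict[str, str] = field(default_factory=dict)       # HL_down/HL_up/none
    te_log2fc: dict[str, float] = field(default_factory=dict)
    te_label: dict[str, str] = field(default_factory=dict)
    psi_control: dict[str, float] = field(default_factory=dict)
    psi_kd: dict[str, float] = field(default_factory=dict)
    psi_label: dict[str, str] = field(default_factory=dict)
    m6a_sites: list[M6ASite] = field(default_factory=list)
    reader_rbp: str = ""
    model_labels: dict[str, int] = field(default_factory=dict)   # gene -> 0/1
    true_edit_keys: set = field(default_factory=set)


# -- transcriptome ---------------------------------------------------------------


def gen_transcriptome(cfg: SimulationConfig):
    """Toy genome and annotation with DRACH-anchored m6A sites.

    Returns (genome, txome, tx_sequences, truth) where genome maps chrom ->
    sequence string and truth carries the planted m6A sites.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom = "chr1"
    cursor = int(rng.integers(*cfg.gap_range))
    transcripts = {}
    gene_meta = []
    for gi in range(cfg.n_genes):
        gene = f"G{gi:04d}"
        tid = f"T{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(cfg.exon_range[0], cfg.exon_range[1] + 1))
        exons = []
        start = cursor
        for _ in range(n_exons):
            length = int(rng.integers(*cfg.exon_len_range))
            exons.append((start, start + length))
            start = start + length + int(rng.integers(*cfg.intron_len_range))
        cursor = exons[-1][1] + int(rng.integers(*cfg.gap_range))
        total = sum(e - s for s, e in exons)
        utr5 = int(rng.integers(*cfg.utr5_range))
        utr3 = int(rng.integers(*cfg.utr3_range))
        utr5 = min(utr5, total // 4)
        utr3 = min(utr3, total // 4)
        cds_start_t, cds_end_t = utr5, total - utr3
        tx = TranscriptModel(
            transcript_id=tid, gene_id=gene, chrom=chrom, strand=strand,
            exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
            cds_start_t=cds_start_t, cds_end_t=cds_end_t,
        )
        transcripts[tid] = tx
        gene_meta.append((gene, tx))
    genome_len = cursor + 100
    seq = rng.choice(BASES, size=genome_len)

    truth = GroundTruth()
    for gene, tx in gene_meta:
        if rng.random() >= cfg.p_m6a_gene:
            continue
        n_sites = 1 + int(rng.poisson(cfg.m6a_per_gene_mean - 1.0))
        occupied: set[int] = set()
        for _ in range(n_sites):
            for _attempt in range(20):
                tpos = int(round(tx.cds_end_t + rng.normal(0.0, cfg.m6a_stop_sd)))
                tpos = max(5, min(len(tx) - 6, tpos))
                gpos = [tx.transcript_to_genome(t) for t in range(tpos - 2, tpos + 3)]
                lo, hi = min(gpos), max(gpos)
                window = set(range(lo, hi + 1))
                if hi - lo != 4 or window & occupied:
                    continue  # motif must sit inside one exon, clear of other motifs
                motif = "GGACT" if tx.strand == "+" else "AGTCC"  # revcomp
                seq[lo:hi + 1] = list(motif)
                center = tx.transcript_to_genome(tpos)
                truth.m6a_sites.append(M6ASite(
                    chrom=tx.chrom, pos=center, strand=tx.strand,
                    rates=(), source="GLORI", gene_ids=(gene,),
                ))
                occupied |= window
                break
    genome = {chrom: "".join(seq)}
    txome = Transcriptome(transcripts)
    tx_sequences = {
        tid: transcript_sequence(genome, tx) for tid, tx in transcripts.items()
    }
    return genome, txome, tx_sequences, truth


def transcript_sequence(genome: dict[str, str], tx: TranscriptModel) -> str:
    parts = [genome[tx.chrom][e.start:e.end] for e in tx.exons]
    s = "".join(parts)
    if tx.strand == "-":
        s = s.translate(_COMP)[::-1]
    return s


def write_fasta(genome: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            s = genome[chrom]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def write_gtf(txome: Transcriptome, path: str) -> None:
    """Ensembl-dialect GTF (1-based closed) with exon and CDS features."""
    with open(path, "w") as fh:
        for tid in sorted(txome.transcripts):
            tx = txome.transcripts[tid]
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            for e in tx.exons:
                fh.write(f"{tx.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t{tx.strand}\t.\t{attrs}\n")
            if tx.is_coding:
                for t0, t1 in _cds_genomic_blocks(tx):
                    fh.write(f"{tx.chrom}\tsim\tCDS\t{t0 + 1}\t{t1}\t.\t{tx.strand}\t0\t{attrs}\n")


def _cds_genomic_blocks(tx: TranscriptModel) -> list[tuple[int, int]]:
    gpos = sorted(tx.transcript_to_genome(t) for t in range(tx.cds_start_t, tx.cds_end_t))
    blocks, start, prev = [], gpos[0], gpos[0]
    for g in gpos[1:]:
        if g != prev + 1:
            blocks.append((start, prev + 1))
            start = g
        prev = g
    blocks.append((start, prev + 1))
    return blocks


# -- decay experiment ------------------------------------------------------------


def plant_decay_truth(cfg: SimulationConfig, genes: list[str]) -> GroundTruth:
    """Sample per-gene degradation rates and plant half-life changes."""
    rng = np.random.default_rng(cfg.seed + 1)
    truth = GroundTruth()
    n = len(genes)
    base_k = np.exp(rng.normal(cfg.k_log_mean, cfg.k_log_sd, size=n))
    n_planted = int(round(cfg.planted_hl_fraction * n))
    planted = rng.choice(n, size=n_planted, replace=False)
    down = set(planted[: n_planted // 2])
    up = set(planted[n_planted // 2:])
    for i, gene in enumerate(genes):
        k = float(base_k[i])
        if i in down:
            # control decays faster: shorter control half-life -> HL_down
            truth.k_control[gene] = k * cfg.planted_hl_fold
            truth.k_kd[gene] = k
            truth.hl_label[gene] = "HL_down"
        elif i in up:
            truth.k_control[gene] = k
            truth.k_kd[gene] = k * cfg.planted_hl_fold
            truth.hl_label[gene] = "HL_up"
        else:
            truth.k_control[gene] = k
            truth.k_kd[gene] = k
            truth.hl_label[gene] = "none"
    return truth


def gen_decay_experiment(cfg: SimulationConfig, truth: GroundTruth) -> CountMatrix:
    """Poisson time-course counts with ERCC rows, at fixed per-library depth.

    Each library is sequenced to a fixed total (the 0 h libraries 4x deeper),
    so per-gene counts stay near ``depth`` while mRNA decays and the ERCC
    share of the library grows: the decay signal lives in the mRNA:ERCC
    ratio, exactly what spike-in normalization recovers.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    genes = sorted(truth.k_control)
    gene_factor = np.exp(rng.normal(0.0, cfg.gene_factor_sd, size=len(genes)))
    ercc_ids = [f"ERCC-{i:05d}" for i in range(cfg.n_ercc)]
    # ERCC molar amounts: fixed per sample, a small fraction of the 0 h mRNA
    # pool (spike-ins are a minor library component) but enough total counts
    # that the spike-in denominator adds negligible noise
    ercc_level = np.exp(rng.normal(0.0, 0.4, size=cfg.n_ercc))
    ercc_level *= cfg.ercc_fraction * gene_factor.sum() / ercc_level.sum()
    # total sequenced material per library (base scale): mean gene count == depth at t=0
    s0 = cfg.depth / gene_factor.mean()
    total_reads = s0 * (gene_factor.sum() + ercc_level.sum())
    columns, data, samples = [], [], []
    for cond, k_map in (("shControl", truth.k_control), ("shMETTL3", truth.k_kd)):
        k = np.array([k_map[g] for g in genes])
        for t in cfg.times_h:
            libscale = cfg.deep_t0_scale if t == 0 else 1.0
            q = gene_factor * np.exp2(-k * t)  # molar quantity per gene
            s = total_reads * libscale / (q.sum() + ercc_level.sum())
            for rep in range(1, cfg.n_replicates + 1):
                name = f"{cond}_t{t:g}_r{rep}"
                col = np.concatenate([rng.poisson(q * s), rng.poisson(ercc_level * s)])
                columns.append(name)
                data.append(col)
                samples.append(SampleInfo(name, cond, float(t), rep))
    counts = pd.DataFrame(
        np.column_stack(data), index=genes + ercc_ids, columns=columns
    )
    return CountMatrix(counts, samples)


# -- TE / splicing ---------------------------------------------------------------


def plant_te_psi_truth(cfg: SimulationConfig, genes: list[str],
                       truth: GroundTruth | None = None) -> GroundTruth:
    rng = np.random.default_rng(cfg.seed + 3)
    truth = truth or GroundTruth()
    n = len(genes)
    n_te = int(round(cfg.planted_te_fraction * n))
    te_idx = rng.choice(n, size=n_te, replace=False)
    te_up = set(te_idx[: n_te // 2])
    te_down = set(te_idx[n_te // 2:])
    lfc = math.log2(cfg.planted_te_fold)
    for i, g in enumerate(genes):
        if i in te_up:
            truth.te_log2fc[g], truth.te_label[g] = lfc, "up"
        elif i in te_down:
            truth.te_log2fc[g], truth.te_label[g] = -lfc, "down"
        else:
            truth.te_log2fc[g], truth.te_label[g] = 0.0, "none"
    n_psi = int(round(cfg.planted_psi_fraction * n))
    psi_idx = set(rng.choice(n, size=n_psi, replace=False).tolist())
    for i, g in enumerate(genes):
        base = float(rng.uniform(0.25, 0.75))
        if i in psi_idx:
            shift = cfg.planted_psi_shift if rng.random() < 0.5 else -cfg.planted_psi_shift
            psi_c = min(0.95, max(0.05, base + shift / 2))
            psi_k = min(0.95, max(0.05, base - shift / 2))
            label = "PSI_up" if psi_c > psi_k else "PSI_down"
        else:
            psi_c = psi_k = base
            label = "none"
        truth.psi_control[g], truth.psi_kd[g] = psi_c, psi_k
        truth.psi_label[g] = label
    return truth


def gen_te_experiment(cfg: SimulationConfig, truth: GroundTruth
                      ) -> tuple[CountMatrix, CountMatrix]:
    """Matched RPF/RNA count pair; RPF rate = RNA abundance x TE."""
    rng = np.random.default_rng(cfg.seed + 4)
    genes = sorted(truth.te_log2fc)
    abund = np.exp(rng.normal(0.0, 0.5, size=len(genes)))
    lfc = np.array([truth.te_log2fc[g] for g in genes])
    frames = {}
    for assay in ("rna", "rpf"):
        cols, data, samples = [], [], []
        for cond in ("shControl", "shMETTL3"):
            te = np.exp2(lfc) if cond == "shControl" else np.ones_like(lfc)
            for rep in range(1, cfg.te_replicates + 1):
                name = f"{assay}_{cond}_r{rep}"
                mu = cfg.depth * abund * (te if assay == "rpf" else 1.0)
                cols.append(name)
                data.append(rng.poisson(mu))
                samples.append(SampleInfo(name, cond, 0.0, rep))
        frames[assay] = CountMatrix(
            pd.DataFrame(np.column_stack(data), index=genes, columns=cols), samples
        )
    return frames["rpf"], frames["rna"]


def gen_psi_experiment(cfg: SimulationConfig, truth: GroundTruth,
                       txome: Transcriptome | None = None) -> list[ExonEvent]:
    """Cassette-exon junction counts; inclusion probability is Psi-weighted by effective length."""
    rng = np.random.default_rng(cfg.seed + 5)
    li, ls = cfg.inclusion_eff_len, cfg.skipping_eff_len
    events = []
    for g in sorted(truth.psi_control):
        if txome is not None and g in txome.representative:
            tx = txome.rep_transcript(g)
            exon = tx.exons[len(tx.exons) // 2]
        else:
            exon = GenomicInterval("chr1", 1000, 1200, "+")
        inclusion, skipping = {}, {}
        for cond, psi in (("shControl", truth.psi_control[g]),
                          ("shMETTL3", truth.psi_kd[g])):
            p_incl = psi * li / (psi * li + (1 - psi) * ls)
            for rep in range(1, cfg.te_replicates + 1):
                name = f"{cond}_r{rep}"
                i = int(rng.binomial(cfg.junction_depth, p_incl))
                inclusion[name] = i
                skipping[name] = cfg.junction_depth - i
        events.append(ExonEvent(
            event_id=f"SE_{g}", gene_id=g, exon=exon,
            inclusion=inclusion, skipping=skipping, li=li, ls=ls,
        ))
    return events


def psi_samples_by_condition(cfg: SimulationConfig) -> dict[str, list[str]]:
    return {
        cond: [f"{cond}_r{r}" for r in range(1, cfg.te_replicates + 1)]
        for cond in ("shControl", "shMETTL3")
    }


# -- RBP tracks and model labels -------------------------------------------------


def gen_readout_features(cfg: SimulationConfig, truth: GroundTruth,
                         txome: Transcriptome, seed_offset: int = 0
                         ) -> tuple[list[RBPTrack], GroundTruth]:
    """RBP tracks whose reader-score context is coupled to planted labels.

    The reader binds near an m6A site on most genes (probability
    ``p_signal``), but binds strongly (``reader_score``) on positive-label
    genes and weakly (``background_score``) on negatives — the readout tracks
    binding strength, not mere presence. Genes the reader misses get, with
    probability ``p_background_site``, a weak site placed uniformly in the
    gene span. Decoy tracks are uniform and label-independent throughout.
    ``seed_offset`` lets callers emulate distinct cell types with their own
    planted rule.
    """
    if not 0.0 <= cfg.p_signal <= 1.0:
        raise ValueError("p_signal must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed + 6 + seed_offset)
    sites_by_gene: dict[str, list[M6ASite]] = {}
    for s in truth.m6a_sites:
        for g in s.gene_ids:
            sites_by_gene.setdefault(g, []).append(s)
    genes = sorted(sites_by_gene)
    labels = {g: int(rng.random() < 0.5) for g in genes}
    truth.model_labels = labels
    truth.reader_rbp = cfg.reader_rbp
    rbp_names = [f"RBP{i:02d}" for i in range(cfg.n_rbp)]
    if cfg.reader_rbp not in rbp_names:
        rbp_names[0] = cfg.reader_rbp
    tracks = []
    for rbp in rbp_names:
        is_reader = rbp == cfg.reader_rbp
        sites: list[RBPBindingSite] = []
        for g in genes:
            tx = txome.rep_transcript(g)
            span_lo, span_hi = tx.exons[0].start, tx.exons[-1].end
            if is_reader and rng.random() < cfg.p_signal:
                anchor = sites_by_gene[g][int(rng.integers(len(sites_by_gene[g])))]
                offset = int(rng.integers(*cfg.reader_offset_range))
                sign = -1 if rng.random() < 0.5 else 1
                start = max(0, anchor.pos + sign * offset)
                params = cfg.reader_score if labels[g] == 1 else cfg.background_score
                score = max(0.1, rng.normal(*params))
                sites.append(RBPBindingSite(
                    rbp, GenomicInterval(tx.chrom, start, start + cfg.reader_site_len,
                                         tx.strand), float(score)))
            elif rng.random() < cfg.p_background_site:
                start = int(rng.integers(span_lo, max(span_lo + 1, span_hi - cfg.reader_site_len)))
                score = max(0.1, rng.normal(*cfg.background_score))
                sites.append(RBPBindingSite(
                    rbp, GenomicInterval(tx.chrom, start, start + cfg.reader_site_len,
                                         tx.strand), float(score)))
        tracks.append(RBPTrack(rbp, sites))
    return tracks, truth


def gen_expression_dependency(cfg: SimulationConfig, genes: list[str]
                              ) -> tuple[pd.DataFrame, pd.Series]:
    """Uninformative per-tissue expression and dependency tables (noise features)."""
    rng = np.random.default_rng(cfg.seed + 7)
    tissues = [f"tissue{i}" for i in range(cfg.n_tissues)]
    expr = pd.DataFrame(
        np.exp(rng.normal(2.0, 1.0, size=(len(genes), cfg.n_tissues))),
        index=genes, columns=tissues,
    )
    dep = pd.Series(rng.normal(0.0, 0.3, size=len(genes)), index=genes)
    return expr, dep


def gen_glori_tables(cfg: SimulationConfig, truth: GroundTruth
                     ) -> tuple[list[M6ASite], list[M6ASite]]:
    """GLORI-style control and knockdown site tables around the planted truth.

    Control: true sites with confident rates, plus low-rate noise sites and a
    few sites that also appear in the knockdown table (to be excluded).
    """
    rng = np.random.default_rng(cfg.seed + 8)
    ctrl, kd = [], []
    for s in truth.m6a_sites:
        rates = tuple(float(r) for r in rng.uniform(0.3, 0.9, size=2))
        ctrl.append(M6ASite(s.chrom, s.pos, s.strand, rates=rates,
                            gene_ids=s.gene_ids))
    n = len(ctrl)
    for i in range(max(2, n // 10)):
        pos = int(rng.integers(0, 10_000_000))
        rates = (float(rng.uniform(0.0, 0.1)), float(rng.uniform(0.1, 0.3)))
        ctrl.append(M6ASite("chr1", pos, "+", rates=rates))
    for s in truth.m6a_sites[: max(1, n // 20)]:
        kd.append(M6ASite(s.chrom, s.pos, s.strand,
                          rates=(0.2, 0.2), gene_ids=s.gene_ids))
    return ctrl, kd


# -- editing data ----------------------------------------------------------------


def gen_editing_data(cfg: SimulationConfig, truth: GroundTruth
                     ) -> tuple[list[EditingSiteRecord], set]:
    """Sampled editing matrices with true sites above and false sites below the filters."""
    rng = np.random.default_rng(cfg.seed + 9)
    records = []
    snp_mask: set[tuple[str, int]] = set()
    pos_pool = iter(rng.choice(5_000_000, size=5000, replace=False).tolist())
    for _ in range(cfg.n_true_edit_sites):
        pos = next(pos_pool)
        rate = float(rng.uniform(0.15, 0.6))
        cov = tuple(int(max(20, rng.negative_binomial(8, 8 / (8 + cfg.edit_coverage_mean))))
                    for _ in range(3))
        mut = tuple(max(2, int(rng.binomial(c, rate))) for c in cov)
        rec = EditingSiteRecord("chr1", pos, "+", cov, mut, 100, 0)
        records.append(rec)
        truth.true_edit_keys.add(rec.key)
    for _ in range(cfg.n_false_edit_sites):
        pos = next(pos_pool)
        mode = rng.integers(4)
        cov = (100, 100, 100)
        if mode == 0:      # below rate floor in every replicate
            mut = (2, 3, 2)
        elif mode == 1:    # fails the control ratio
            mut = (30, 30, 30)
            records.append(EditingSiteRecord("chr1", pos, "+", cov, mut, 100, 25))
            continue
        elif mode == 2:    # single mutation
            cov = (20, 20, 20)
            mut = (1, 1, 1)
        else:              # SNP overlap
            mut = (30, 30, 30)
            snp_mask.add(("chr1", pos))
        records.append(EditingSiteRecord("chr1", pos, "+", cov, mut, 100, 0))
    records.sort(key=lambda r: r.pos)
    return records, snp_mask


def editing_boundary_fixture() -> tuple[list[EditingSiteRecord], set, set]:
    """Deterministic filter-boundary cases: exact counts, no sampling.

    Returns (records, snp_mask, expected_retained_keys). Each failing site
    breaks exactly one gate.
    """
    mk = EditingSiteRecord
    records = [
        mk("chr1", 100, "+", (100, 100, 100), (10, 12, 8), 100, 0),    # clean pass
        mk("chr1", 200, "+", (100, 100, 100), (5, 5, 5), 100, 0),      # exact 5% floor: pass
        mk("chr1", 300, "+", (100, 100, 100), (4, 10, 10), 100, 0),    # one rep at 4%: fail
        mk("chr1", 400, "+", (100, 100, 100), (50, 50, 50), 100, 40),  # ratio 1.25: fail
        mk("chr1", 500, "+", (20, 20, 20), (1, 2, 2), 20, 0),          # one mutation: fail
        mk("chr1", 600, "+", (100, 100, 100), (30, 30, 30), 100, 0),   # SNP overlap: fail
        mk("chr1", 700, "+", (100, 100, 100), (10, 10, 4), 100, 0),    # 2-of-3 reps: fail
        mk("chr1", 800, "+", (200, 200, 200), (199, 20, 20), 200, 0),  # 99.5% > cap: fail
        mk("chr1", 900, "+", (100, 100, 100), (50, 50, 50), 100, 30),  # ratio 5/3 >= 1.5: pass
        mk("chr1", 950, "+", (100, 100, 0), (10, 10, 0), 100, 0),      # zero coverage rep: fail
    ]
    snp_mask = {("chr1", 600)}
    expected = {("chr1", 100, "+"), ("chr1", 200, "+"), ("chr1", 900, "+")}
    return records, snp_mask, expected


def exonic_adenosines(genome: dict[str, str], txome: Transcriptome,
                      exclude: set[tuple[str, int]] | None = None,
                      limit: int | None = None,
                      seed: int = 0) -> list[tuple[str, int, str]]:
    """Candidate background A positions (exonic, strand-aware) for proximity profiles."""
    exclude = exclude or set()
    out = []
    for gene in txome.genes:
        tx = txome.rep_transcript(gene)
        for e in tx.exons:
            block = genome[tx.chrom][e.start:e.end]
            target = "A" if tx.strand == "+" else "T"
            for i, base in enumerate(block):
                if base == target and (tx.chrom, e.start + i) not in exclude:
                    out.append((tx.chrom, e.start + i, tx.strand))
    if limit is not None and len(out) > limit:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(out), size=limit, replace=False)
        out = [out[i] for i in sorted(idx)]
    return out


# -- convenience: everything at once --------------------------------------------


def simulate_all(cfg: SimulationConfig):
    """Generate the full linked dataset: transcriptome, counts, tracks, tables.

    Returns a dict of all artifacts plus the merged GroundTruth.
    """
    genome, txome, tx_seqs, truth = gen_transcriptome(cfg)
    genes = txome.genes
    decay_truth = plant_decay_truth(cfg, genes)
    truth.k_control, truth.k_kd = decay_truth.k_control, decay_truth.k_kd
    truth.hl_label = decay_truth.hl_label
    plant_te_psi_truth(cfg, genes, truth)
    decay = gen_decay_experiment(cfg, truth)
    rpf, rna = gen_te_experiment(cfg, truth)
    events = gen_psi_experiment(cfg, truth, txome)
    tracks, truth = gen_readout_features(cfg, truth, txome)
    expr, dep = gen_expression_dependency(cfg, genes)
    glori_ctrl, glori_kd = gen_glori_tables(cfg, truth)
    editing, snp_mask = gen_editing_data(cfg, truth)
    return {
        "genome": genome, "txome": txome, "tx_sequences": tx_seqs,
        "decay_counts": decay, "rpf": rpf, "rna": rna, "exon_events": events,
        "rbp_tracks": tracks, "expression": expr, "dependency": dep,
        "glori_control": glori_ctrl, "glori_kd": glori_kd,
        "editing_records": editing, "snp_mask": snp_mask,
        "truth": truth,
    }
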