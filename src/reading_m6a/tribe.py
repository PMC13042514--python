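"""HyperTRIBE editing-site calling and m6A-proximity analysis.

An RBP fused to a hyperactive ADAR deposits A-to-I edits near its binding
sites; edits appear as A-to-G mismatches in RNA-seq. Site calling applies,
per fusion replicate: editing rate within [5%, 99%], rate at least 1.5x the
ADAR-only control, at least two mutant reads, and no overlap with an
annotated SNP; a site is retained when all three replicates pass and the
mean fusion editing rate is at least 5%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

RATE_MIN = 0.05
RATE_MAX = 0.99
CONTROL_RATIO = 1.5
MIN_MUTATIONS = 2
N_REPLICATES = 3
MEAN_RATE_MIN = 0.05


@dataclass(frozen=True)
class EditingSiteRecord:
    chrom: str
    pos: int
    strand: str
    coverage: tuple[int, ...]   # per fusion replicate
    mutations: tuple[int, ...]  # per fusion replicate
    control_coverage: int
    control_mutations: int

    def __post_init__(self) -> None:
        if len(self.coverage) != len(self.mutations):
            raise ValueError("coverage/mutation replicate counts differ")
        for cov, mut in zip(self.coverage, self.mutations):
            if not 0 <= mut <= cov:
                raise ValueError("mutations must satisfy 0 <= mut <= coverage")

    @property
    def rates(self) -> tuple[float, ...]:
        return tuple(m / c if c > 0 else math.nan
                     for c, m in zip(self.coverage, self.mutations))

    @property
    def control_rate(self) -> float:
        if self.control_coverage <= 0:
            return 0.0
        return self.control_mutations / self.control_coverage

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


@dataclass
class EditingCallSet:
    sites: list[EditingSiteRecord]
    mean_rates: dict[tuple[str, int, str], float]
    target_genes: set[str]


def _replicate_passes(rate: float, mut: int, control_rate: float) -> bool:
    if math.isnan(rate):
        return False  # zero coverage
    if not RATE_MIN <= rate <= RATE_MAX:
        return False
    # control rate 0: any editing exceeds 1.5 x 0
    if rate < CONTROL_RATIO * control_rate:
        return False
    return mut >= MIN_MUTATIONS


def call_editing_sites(
    records: list[EditingSiteRecord],
    snp_mask: set[tuple[str, int]] | None = None,
    gene_lookup=None,
) -> EditingCallSet:
    """Apply the editing-site filters and collect target genes.

    ``snp_mask`` holds (chrom, pos) of annotated SNPs; masked positions never
    pass. ``gene_lookup(chrom, pos, strand)`` returns gene ids covering a
    site (strand-matched); all overlapping genes count as targets.
    """
    snp_mask = snp_mask or set()
    kept, mean_rates, genes = [], {}, set()
    for rec in records:
        if len(rec.coverage) < N_REPLICATES:
            raise ValueError(f"{rec.key}: need >= {N_REPLICATES} fusion replicates")
        if (rec.chrom, rec.pos) in snp_mask:
            continue
        ctrl = rec.control_rate
        if not all(_replicate_passes(r, m, ctrl)
                   for r, m in zip(rec.rates, rec.mutations)):
            continue
        mean_rate = float(np.mean(rec.rates))
        if mean_rate < MEAN_RATE_MIN:
            continue
        kept.append(rec)
        mean_rates[rec.key] = mean_rate
        if gene_lookup is not None:
            genes.update(gene_lookup(rec.chrom, rec.pos, rec.strand))
    kept.sort(key=lambda r: r.key)
    return EditingCallSet(kept, mean_rates, genes)


def proximity_profile(
    calls: EditingCallSet,
    m6a_sites,
    window: int = 1000,
    bins: int = 50,
    background_positions: list[tuple[str, int, str]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Density of edits around m6A sites, signed and strand-oriented.

    For each m6A site, edits on the same chromosome within ``window`` nt
    contribute their signed distance (downstream positive; flipped on the
    minus strand). If ``background_positions`` (candidate non-m6A adenosine
    positions) is given, an equal-size seeded random subset anchors a
    background profile. Returns a frame with bin centers and densities.
    """
    edit_by_chrom: dict[str, np.ndarray] = {}
    for rec in calls.sites:
        edit_by_chrom.setdefault(rec.chrom, []).append(rec.pos)
    edit_by_chrom = {c: np.sort(np.array(p)) for c, p in edit_by_chrom.items()}
    if not edit_by_chrom or not m6a_sites:
        raise ValueError("both edit calls and m6A sites are required")
    shared = edit_by_chrom.keys() & {s.chrom for s in m6a_sites}
    if not shared:
        raise ValueError("edit calls and m6A sites share no chromosome")

    def distances(anchors) -> np.ndarray:
        out = []
        for chrom, pos, strand in anchors:
            edits = edit_by_chrom.get(chrom)
            if edits is None:
                continue
            lo = np.searchsorted(edits, pos - window, side="left")
            hi = np.searchsorted(edits, pos + window, side="right")
            d = edits[lo:hi] - pos
            if strand == "-":
                d = -d
            out.append(d)
        return np.concatenate(out) if out else np.array([])

    fg = distances((s.chrom, s.pos, s.strand) for s in m6a_sites)
    edges = np.linspace(-window, window, bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    fg_density, _ = (np.histogram(fg, bins=edges, density=True)
                     if fg.size else (np.zeros(bins), edges))
    out = pd.DataFrame({"bin_center": centers, "m6a_density": fg_density})
    if background_positions is not None:
        rng = np.random.default_rng(seed)
        n = min(len(m6a_sites), len(background_positions))
        idx = rng.choice(len(background_positions), size=n, replace=False)
        bg_anchors = [background_positions[i] for i in idx]
        bg = distances(bg_anchors)
        bg_density, _ = (np.histogram(bg, bins=edges, density=True)
                         if bg.size else (np.zeros(bins), edges))
        out["background_density"] = bg_density
    return out


def overlap_fisher(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[float, float]:
    """Two-sided Fisher exact test of gene-set overlap within a universe.

    Returns (odds ratio, p). The odds ratio is the sample OR with a Haldane
    0.5 correction when any margin cell is zero.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe - set_a - set_b)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orat = (a * d) / (b * c)
    return float(orat), float(p)


# -- I/O ------------------------------------------------------------------------

def read_editing_tsv(path: str) -> list[EditingSiteRecord]:
    """TSV: chrom, pos, strand, cov_rep1..3, mut_rep1..3, cov_control, mut_control."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cov_cols = sorted(c for c in df.columns if c.startswith("cov_rep"))
    mut_cols = sorted(c for c in df.columns if c.startswith("mut_rep"))
    return [
        EditingSiteRecord(
            str(r["chrom"]), int(r["pos"]), str(r["strand"]),
            tuple(int(r[c]) for c in cov_cols),
            tuple(int(r[c]) for c in mut_cols),
            int(r["cov_control"]), int(r["mut_control"]),
        )
        for _, r in df.iterrows()
    ]


def calls_to_bed(calls: EditingCallSet, path: str) -> None:
    with open(path, "w") as fh:
        for rec in calls.sites:
            rate = calls.mean_rates[rec.key]
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.pos + 1}\tedit\t{rate:.4f}\t{rec.strand}\n")
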