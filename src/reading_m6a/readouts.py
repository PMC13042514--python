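"""Quantify the three m6A readouts from count-level inputs.

Readouts compare shControl (normal m6A) against shMETTL3 (m6A-disrupted):

* mRNA half-life, from actinomycin-D time courses anchored on ERCC spike-ins,
  fitting log2(A_t / A_0 * delta) = -k t at t = 3 h and 6 h;
* translation efficiency (TE = RPF abundance / mRNA abundance), tested at the
  relaxed thresholds of 1.5-fold and p < 0.05;
* exon inclusion (Psi), with a delta-Psi >= 0.1 and FDR < 0.05 gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ERCC_PREFIX = "ERCC-"
TIME_POINTS = (0, 3, 6)  # hours used for rate fitting
HL_FOLD = 1.5
TE_FOLD = 1.5
TE_P = 0.05
DPSI_MIN = 0.1
PSI_FDR = 0.05


@dataclass(frozen=True)
class SampleInfo:
    sample: str
    condition: str
    time_h: float
    replicate: int


class CountMatrix:
    """Gene x sample counts with sample metadata; ERCC spike-in rows flagged by id prefix."""

    def __init__(self, counts: pd.DataFrame, samples: list[SampleInfo]):
        by_name = {s.sample: s for s in samples}
        missing = set(counts.columns) - set(by_name)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        self.counts = counts
        self.samples = [by_name[c] for c in counts.columns]

    @property
    def ercc_mask(self) -> pd.Series:
        return self.counts.index.str.startswith(ERCC_PREFIX)

    def samples_for(self, condition: str, time_h: float | None = None) -> list[str]:
        return [
            s.sample for s in self.samples
            if s.condition == condition and (time_h is None or s.time_h == time_h)
        ]

    @classmethod
    def from_tsv(cls, counts_path: str, sample_sheet_path: str) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
        sheet = pd.read_csv(sample_sheet_path, sep="\t", comment="#")
        samples = [
            SampleInfo(str(r["sample"]), str(r["condition"]), float(r["time_h"]),
                       int(r["replicate"]))
            for _, r in sheet.iterrows()
        ]
        return cls(counts, samples)


@dataclass
class DecayEstimate:
    gene_id: str
    condition: str
    k: float          # combined degradation rate, 1/h
    k3: float
    k6: float
    half_life: float  # 1/k in h; +inf when k <= 0
    delta3: float
    delta6: float


@dataclass
class TEChange:
    gene_id: str
    log2fc: float     # control minus knockdown, log2 TE
    pvalue: float
    direction: str    # "up", "down", or "none"


@dataclass
class ExonEvent:
    """A cassette (skipped) exon with per-sample junction counts.

    ``inclusion``/``skipping`` map sample name -> junction read count;
    ``li``/``ls`` are the effective lengths of the inclusion and skipping forms.
    """

    event_id: str
    gene_id: str
    exon: "object"  # GenomicInterval; kept loose to avoid a hard import cycle
    inclusion: dict[str, int]
    skipping: dict[str, int]
    li: float
    ls: float


@dataclass
class ReadoutCall:
    unit_id: str
    category: str     # HL_down/HL_up/TE_down/TE_up/PSI_down/PSI_up/none
    effect_size: float
    significance: float  # p or FDR where applicable, nan otherwise
    reason: str = ""


class NormalizationError(ValueError):
    pass


def ercc_normalize(cm: CountMatrix) -> CountMatrix:
    """Scale each sample by its ERCC spike-in total and drop the ERCC rows.

    Spike-ins are added at a fixed amount per sample, so dividing by the
    per-sample ERCC total puts all samples on an absolute scale that is exactly
    invariant to library depth.
    """
    ercc = cm.ercc_mask
    totals = cm.counts.loc[ercc].sum(axis=0)
    bad = totals[totals <= 0]
    if not ercc.any() or len(bad):
        raise NormalizationError(
            f"samples without positive ERCC totals: {list(bad.index) or 'no ERCC rows'}"
        )
    normalized = cm.counts.loc[~ercc].div(totals, axis=1)
    return CountMatrix(normalized, cm.samples)


def _delta_auto(ratios: pd.Series) -> float:
    """delta = min(1, 1/median(A_t/A_0)): corrects only prominent upward drift."""
    med = float(ratios.median())
    if med <= 0:
        return 1.0
    return min(1.0, 1.0 / med)


def fit_decay(
    abs_counts: CountMatrix,
    condition: str,
    delta: float | str = "auto",
) -> tuple[list[DecayEstimate], list[tuple[str, str]]]:
    """Per-gene degradation rates for one condition.

    k_t = -log2(A_t / A_0 * delta_t) / t at t = 3 and 6 h. The combined k is
    the least-squares slope of -log2(A_t/A_0 * delta_t) against t through the
    origin, i.e. a t^2-weighted average of k3 and k6 (0.2*k3 + 0.8*k6): the
    short-time ratio carries the larger relative counting noise, so equal
    weighting would inflate the estimator variance. Half-life is 1/k
    (infinite for k <= 0). Replicates are averaged after normalization.
    Returns (estimates, skipped) where skipped holds (gene, reason) pairs.
    """
    means = {}
    for t in TIME_POINTS:
        cols = abs_counts.samples_for(condition, t)
        if not cols:
            raise ValueError(f"no samples for condition={condition!r} at t={t} h")
        means[t] = abs_counts.counts[cols].mean(axis=1)
    a0 = means[0]
    keep = a0 > 0
    skipped = [(g, "A0=0") for g in a0.index[~keep]]
    estimates = []
    ks, deltas = {}, {}
    for t in (3, 6):
        ratios = (means[t][keep] / a0[keep]).astype(float)
        d = _delta_auto(ratios) if delta == "auto" else float(delta)
        deltas[t] = d
        with np.errstate(divide="ignore"):
            ks[t] = -np.log2(ratios * d) / t
    for gene in a0.index[keep]:
        k3, k6 = float(ks[3][gene]), float(ks[6][gene])
        if not (math.isfinite(k3) and math.isfinite(k6)):
            skipped.append((gene, "zero count at t>0"))
            continue
        # regression through the origin over the two time points:
        # k = sum(t * l_t) / sum(t^2) with l_t = -log2 ratio = k_t * t
        k = (3 * (k3 * 3) + 6 * (k6 * 6)) / (3 * 3 + 6 * 6)
        estimates.append(DecayEstimate(
            gene_id=gene, condition=condition, k=k, k3=k3, k6=k6,
            half_life=(1.0 / k) if k > 0 else math.inf,
            delta3=deltas[3], delta6=deltas[6],
        ))
    return estimates, skipped


def classify_halflife(
    dc_control: list[DecayEstimate],
    dc_kd: list[DecayEstimate],
    fold: float = HL_FOLD,
) -> list[ReadoutCall]:
    """Half-life readout calls at a ``fold`` change of half-life (control / knockdown).

    HL_down: half-life in control <= 1/fold of knockdown (m6A destabilizes);
    HL_up: >= fold. Genes without a finite positive half-life in both
    conditions get category "none" with a reason code.
    """
    ctrl = {e.gene_id: e for e in dc_control}
    kd = {e.gene_id: e for e in dc_kd}
    calls = []
    for gene in sorted(set(ctrl) & set(kd)):
        hc, hk = ctrl[gene].half_life, kd[gene].half_life
        if not (math.isfinite(hc) and math.isfinite(hk) and hc > 0 and hk > 0):
            calls.append(ReadoutCall(gene, "none", math.nan, math.nan, "nonpositive k"))
            continue
        ratio = hc / hk
        log2fc = math.log2(ratio)
        if ratio <= 1.0 / fold:
            cat = "HL_down"
        elif ratio >= fold:
            cat = "HL_up"
        else:
            cat = "none"
        calls.append(ReadoutCall(gene, cat, log2fc, math.nan))
    return calls


def te_change(
    rpf: CountMatrix,
    rna: CountMatrix,
    control: str = "shControl",
    knockdown: str = "shMETTL3",
    fold: float = TE_FOLD,
    alpha: float = TE_P,
    pseudocount: float = 0.5,
) -> list[TEChange]:
    """Translation-efficiency change per gene, control vs knockdown.

    Per replicate, TE = (rpf_g / sum rpf) / (rna_g / sum rna); the statistic is
    a Welch two-sample test on replicate-level log2 TE, a transparent
    methodological substitute for a dedicated differential-TE model.
    Zero counts take a +``pseudocount`` before the ratio. Genes with all-zero
    counts in either assay are skipped.
    """
    genes = rpf.counts.index.intersection(rna.counts.index)
    out = []
    groups = {}
    for cond in (control, knockdown):
        rpf_cols = rpf.samples_for(cond)
        rna_cols = rna.samples_for(cond)
        if len(rpf_cols) < 2 or len(rna_cols) < 2:
            raise ValueError(f"need >=2 replicates per condition, got {cond}")
        rp = rpf.counts.loc[genes, rpf_cols].astype(float)
        rn = rna.counts.loc[genes, rna_cols].astype(float)
        rp_tot, rn_tot = rp.sum(axis=0), rn.sum(axis=0)
        rp = rp.mask(rp == 0, pseudocount)
        rn = rn.mask(rn == 0, pseudocount)
        te = (rp.div(rp_tot, axis=1)).values / (rn.div(rn_tot, axis=1)).values
        groups[cond] = np.log2(te)
    lfc_thresh = math.log2(fold)
    all_zero = (rpf.counts.loc[genes].sum(axis=1) == 0) | (rna.counts.loc[genes].sum(axis=1) == 0)
    for i, gene in enumerate(genes):
        if all_zero.iloc[i]:
            continue
        a, b = groups[control][i], groups[knockdown][i]
        log2fc = float(a.mean() - b.mean())
        t, p = stats.ttest_ind(a, b, equal_var=False)
        p = float(p) if math.isfinite(p) else 1.0
        if abs(log2fc) >= lfc_thresh and p < alpha:
            direction = "up" if log2fc > 0 else "down"
        else:
            direction = "none"
        out.append(TEChange(gene, log2fc, p, direction))
    return out


def compute_psi(inclusion: float, skipping: float, li: float, ls: float) -> float:
    """Percent spliced in: Psi = (I/lI) / (I/lI + S/lS).

    Junction counts are length-normalized because the inclusion form offers
    more mappable junction positions than the skipping form.
    """
    if inclusion < 0 or skipping < 0:
        raise ValueError("junction counts must be non-negative")
    if inclusion == 0 and skipping == 0:
        raise ValueError("Psi undefined for I = S = 0")
    inc = inclusion / li
    skp = skipping / ls
    return inc / (inc + skp)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classify_splicing(
    events: list[ExonEvent],
    samples_by_condition: dict[str, list[str]],
    control: str = "shControl",
    knockdown: str = "shMETTL3",
    dpsi_min: float = DPSI_MIN,
    fdr_max: float = PSI_FDR,
) -> list[ReadoutCall]:
    """Exon-inclusion readout calls.

    Counts are pooled within condition; delta-Psi = Psi(control) - Psi(kd);
    p per event from a two-sided Fisher exact test on the pooled
    [[I_ctrl, S_ctrl], [I_kd, S_kd]] table; BH FDR across events; a call needs
    |delta-Psi| >= ``dpsi_min`` and FDR < ``fdr_max``.
    """
    rows, skipped = [], []
    for ev in events:
        tab = {}
        ok = True
        for cond in (control, knockdown):
            cols = samples_by_condition.get(cond, [])
            i_tot = sum(ev.inclusion.get(c, 0) for c in cols)
            s_tot = sum(ev.skipping.get(c, 0) for c in cols)
            if i_tot + s_tot == 0 or not cols:
                ok = False
                break
            tab[cond] = (i_tot, s_tot)
        if not ok:
            skipped.append(ReadoutCall(ev.event_id, "none", math.nan, math.nan,
                                       "missing condition counts"))
            continue
        psi_c = compute_psi(*tab[control], ev.li, ev.ls)
        psi_k = compute_psi(*tab[knockdown], ev.li, ev.ls)
        _, p = stats.fisher_exact([list(tab[control]), list(tab[knockdown])])
        rows.append((ev.event_id, psi_c - psi_k, float(p)))
    calls = list(skipped)
    if rows:
        fdr = bh_fdr([r[2] for r in rows])
        for (event_id, dpsi, _p), q in zip(rows, fdr):
            if abs(dpsi) >= dpsi_min and q < fdr_max:
                cat = "PSI_up" if dpsi > 0 else "PSI_down"
            else:
                cat = "none"
            calls.append(ReadoutCall(event_id, cat, dpsi, float(q)))
    return calls


def calls_to_frame(calls: list[ReadoutCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.unit_id, c.category, c.effect_size, c.significance, c.reason) for c in calls],
        columns=["unit_id", "category", "effect_size", "significance", "reason"],
    )
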