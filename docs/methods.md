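# Methods

## Scope and model

The package quantifies three post-transcriptional readouts of m6A by
comparing an m6A-normal condition (shControl) against METTL3 knockdown
(shMETTL3), builds single-nucleotide m6A maps, encodes the RBP-binding
context of methylated genes into feature vectors, trains per-cell-type
gradient-boosted classifiers of the readout, and calls RBP target sites
from HyperTRIBE editing matrices. All stages run on plain count-level
inputs (TSV/BED/GTF/FASTA); nothing requires raw reads or alignment.

## Half-life readout

**Model.** First-order decay after transcription inhibition:
log2(A_t / A_0 · δ) = −k·t, with A the ERCC-anchored absolute abundance.
Spike-ins enter each sample at a fixed molar amount, so dividing a sample's
gene counts by its ERCC total removes library depth exactly; the
normalization is invariant to any uniform per-sample scaling (this is what
makes a deliberately ultra-deep 0 h library usable as the common reference
point).

**δ (drift regulator).** δ corrects a global mRNA:ERCC drift at one time
point. We set, per time point, δ = min(1, 1/median_g(A_t/A_0)): if the
median gene appears to *gain* material (a handling artifact), δ rescales
the ratios so the median is non-increasing; otherwise δ = 1. δ can be
overridden with a scalar.

**Rate combination.** k is estimated at t = 3 h and t = 6 h
(k_t = −log2 ratio / t) and combined by least squares through the origin,
k = Σ t·l_t / Σ t² = 0.2·k₃ + 0.8·k₆ (l_t = −log2 ratio). The two
per-timepoint rates have equal absolute log-ratio noise, so dividing by t
gives the 3 h estimate four times the variance of the 6 h one; the
t²-weighted fit is the minimum-variance linear combination and in
simulation lifts half-life recovery (fraction of genes within 10% of
truth at mean depth 200) from ~91% to ~95%. Both k₃ and k₆ are reported.

**Classification.** Half-life = 1/k (infinite when k ≤ 0; such genes are
excluded with a reason code). Fold change is control over knockdown;
|log2 FC| ≥ log2(1.5) calls HL_down (ratio ≤ 1/1.5) or HL_up (≥ 1.5),
boundary inclusive. Replicates (n = 2 by default) are averaged after
normalization — per-replicate fits are unstable at n = 2.

## Translation-efficiency readout

TE = (RPF_g/ΣRPF) / (RNA_g/ΣRNA) per replicate. The test statistic is a
Welch two-sample t-test on replicate-level log2 TE — a transparent
methodological substitute for dedicated differential-TE models, not a
reimplementation of one. Zero counts take +0.5 before the ratio; all-zero
genes are skipped. Calls require |log2 FC| ≥ log2(1.5) and raw p < 0.05
(the threshold is deliberately relaxed and unadjusted; the FDR variant is a
flag). With two replicates the test is conservative (measured type-I error
~2.5% at nominal 5% on 10,000 null genes); power against the generator's
default 4-fold planted shifts at six replicates is ~100%.

## Exon-inclusion readout

Ψ = (I/l_I) / (I/l_I + S/l_S) with effective lengths l_I, l_S of the
inclusion and skipping junctions; Ψ is undefined (flagged) when I = S = 0.
Counts are pooled within condition; per event a two-sided Fisher exact test
on [[I_c, S_c], [I_k, S_k]] gives p, adjusted by Benjamini–Hochberg across
events; a call requires |ΔΨ| ≥ 0.1 and FDR < 0.05. The likelihood-based
machinery of dedicated splicing callers is out of scope; the pooled-count
exact test is the package's substitute, with the identical effect-size gate.

## m6A maps

GLORI-style tables are filtered at modification rate > 0.1 (strict) in
*all* replicates ("both" generalized to ≥ 2), then any site whose exact
(chrom, pos, strand) appears in the knockdown map is excluded — no
tolerance window. MeRIP peaks are projected onto a user-supplied
single-nucleotide catalogue: sites overlapping any peak inherit the
maximum overlapping peak score (peak strand ignored; MeRIP peak BEDs are
commonly unstranded) and must pass the DRACH check, which reads the
strand-oriented genomic 5-mer centered on the site (T ≡ U). The metagene
axis maps 5'UTR → [0,1), CDS → [1,2), 3'UTR → [2,3) by linear scaling
within each segment of the gene's representative transcript; the density
integrates to 1 over mapped sites.

## Feature encoding

Eleven feature sets per m6A-positive gene, computed on one representative
transcript per gene (the longest coding isoform, ties lexicographic —
annotation does not say which isoform carries transcript-coordinate
features, so one deterministic convention is fixed):

1–2. score of the RBP site nearest an m6A site, genome/transcript space.
The anchor is the site achieving the minimum over the gene's m6A sites
(consistent with sets 3–6). 3–6. min and max over the gene's m6A sites of
each site's nearest-RBP distance, both spaces. Point-to-interval distance
is 0 inside, else nt to the nearest covered base; transcript-space
endpoints are converted through the exon model first, and genomic distances
ignore strand. 7. topology: min distance to start/stop codon, mean
metagene position, site count. 8–9. per-tissue expression and dependency
score, joined from user tables (absent genes are masked missing, not
dropped). 10–11. per-k-mer nearest transcript distance from an m6A site
and max occurrence count within ±100 nt of a site (overlapping scan,
windows truncated at transcript ends). The default vocabulary is the 18
DRACH 5-mers — dense features over all 4^6 6-mers are impractical and the
source does not state a vocabulary; any list can be supplied.

Missing values (no binding site on the chromosome/transcript, unexpressed
gene) are NaN, which the tree model treats natively as missing — encoding
them as 0 would collide with genuine overlap (distance 0). Binding scores
are used as-is within a track: the model is tree-based and scale-robust,
and no cross-technology normalization is defined.

Exon-level vectors anchor every RBP feature on the single m6A site closest
to the exon boundary (nearer of the two boundaries, ties toward the 5'
boundary), require that site within 10 kb, take no min/max over sites, and
omit the gene-level-only sets 8–9.

## Readout classifiers

One XGBoost binary classifier per (readout category, cell type); HL_up is
not modeled (too few cases). Negatives are m6A-positive genes that passed
encoding but received no call in that readout layer — the model's scope is
restricted to methylated genes, and the contrast of interest is
responder vs non-responder among them. Hyperparameters are fixed
(max_depth 6, 300 rounds, learning rate 0.1, subsample 0.8): performance
on this problem is insensitive to tuning, so no search is run. Stratified
10-fold CV with a mandatory seed produces out-of-fold scores; AUC is
computed in the Mann–Whitney form (ties half), the ROC is stepwise over
observed thresholds, and sensitivity at 80% specificity takes the maximum
sensitivity among thresholds with specificity ≥ 0.80 (no interpolation).
The feature-set "heuristic search" is greedy forward selection over the
eleven sets, stopping when no candidate improves CV-AUC; each selected
set's gain is the AUC increment at its addition, unpicked sets report
their marginal gain at termination (so both cumulative and marginal
readings are available). Inside the search the CV uses 5 folds
(the search trains ~60 CV rounds; the final model keeps 10). Importance is
mean total gain per feature over fold models; an RBP's score is the max
over its six features, which is robust to credit-splitting across
correlated features of the same track (fully duplicated tracks still route
all gain through one copy — tree ensembles do not split credit between
perfect duplicates).

## HyperTRIBE

Per fusion replicate a site passes iff rate ∈ [0.05, 0.99], rate ≥ 1.5×
the ADAR-only control rate (a zero control rate passes — any editing
exceeds 1.5×0), mutant reads ≥ 2, and the position is not a known SNP;
zero coverage fails that replicate. A site is retained iff all three
replicates pass and the mean fusion rate is ≥ 0.05 (mean over fusion
replicates only). The 5–99% window applies to raw fusion rates, before
the control comparison. Editing-site gene assignment takes every
strand-matched overlapping gene. Proximity profiles histogram signed,
strand-oriented m6A-to-edit distances; the background profile anchors on
an equal-size seeded sample of user-supplied exonic adenosine positions.
Gene-set overlap uses the two-sided Fisher exact test with the sample odds
ratio (Haldane 0.5 correction when a margin cell is zero).

## Synthetic data generator

The generator emulates the study design the pipeline targets: two biological
replicates; time points 0/1/3/6 h with the 0 h library sequenced 4× deeper
(it doubles as the splicing/TE input); multi-exon coding genes with
non-empty UTRs; m6A sites planted as genomic GGACT motifs (strand-aware)
at DRACH-valid positions concentrated around the stop codon (Gaussian,
SD 80 nt); control degradation rates lognormal around 0.3 h⁻¹ (half-life
≈ 3.3 h, log-SD 0.3) with planted 2-fold half-life changes in 20% of genes
(clearly past the 1.5-fold call threshold, so recovery measures power
rather than boundary coin-flips); 4-fold TE shifts and ΔΨ = 0.4 inclusion
shifts in 20% of genes; per-gene abundance lognormal (log-SD 0.3) around a
mean depth of 200 counts.

Decay libraries are sequenced to a fixed per-library total: per-gene
counts stay near the nominal depth while the fixed-amount ERCC share of
the library grows as mRNA decays, so the decay signal lives in the
mRNA:ERCC ratio — the regime real constant-depth libraries produce, and
the one spike-in normalization is designed for. Counts are Poisson
(negative-binomial coverage only in the editing matrices): ratio-of-means
estimators are insensitive to modest overdispersion, which would mainly
widen tolerances.

RBP tracks: twenty, one designated reader. The reader binds near an m6A
site (offset 10–150 nt) on 90% of genes, with score ~ N(8, 1.2) on
positive-label genes and N(2.5, 1.2) on negatives; genes it misses get a
uniformly placed weak site with probability 0.5; decoys are uniform and
label-independent. The planted signal therefore lives primarily in the
nearest-site *score* — the readout tracks binding strength, not mere
presence — which is the structure under which RBP-score feature sets carry
the largest AUC gain. Model labels are drawn from the planted rule, not
from running the readout callers, keeping model tests independent of
caller correctness. A `seed_offset` re-draws the rule to emulate a second
cell type with its own reader, used for the cross-cell-type degradation
check.

Editing matrices contain sampled true sites comfortably above all gates,
sampled failures below single gates, plus a fully deterministic
boundary-case fixture (exact counts: rate 0.04 vs the 0.05 floor, control
ratio 1.25 vs 1.5, 1 vs 2 mutations, SNP overlap, 2-of-3 replicates,
99.5% vs the 99% cap) whose expected call set is known exactly.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: alignment and counting artifacts,
overdispersed biological replicate variation (n = 2 Poisson replicates are
cleaner than real biology), isoform mixtures, correlated RBP binding
across tracks, realistic score distributions of heterogeneous CLIP
technologies, GC/mappability biases, and incomplete METTL3 knockdown.
Quantities like the model AUROC on synthetic signal characterize the
pipeline's correctness and power under its stated noise model, not
expected performance on experimental data.

## Numerical and degenerate-input choices

0-based half-open coordinates internally; GTF converted on read. Exon-miss
coordinate conversion returns None, not an error. Nearest-site ties break
toward the higher score, then the leftmost start. Fisher p-values come
from `scipy.stats.fisher_exact` (verified against full hypergeometric
enumeration to 1e-10 in tests); BH from statsmodels. ERCC-unnormalizable
samples (zero spike-in total), A₀ = 0 genes, single-class ROC inputs,
empty metagene profiles and missing conditions all raise or skip with
explicit reason codes rather than propagating NaN.

## Problem sizes

Default test and acceptance runs use 1,000 genes for decay recovery,
10,000 units for null-rate checks, 250–300 genes for model training (≈270
labeled units, 166 features), 10 seeded repetitions for importance-rank
stability, and 100 random instances per brute-force oracle comparison.
These sizes give stable Monte-Carlo estimates (binomial SE ≤ ~1.5 points
on reported percentages) while keeping a full run in minutes on one CPU.

## Known limitations

The TE and splicing statistics are deliberate transparent substitutes for
Xtail-class and rMATS-class models and will differ from them on real data;
δ's median rule corrects only global drift, not gene-specific artifacts;
the representative-transcript convention discards isoform-specific
binding context; k-mer features default to the DRACH vocabulary rather
than all 6-mers; and per-cell-line performance numbers from the original
deposited datasets are not reproducible here by design — all empirical
claims in this package are about the synthetic conditions above.
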