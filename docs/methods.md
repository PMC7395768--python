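# Methods

This note documents the models, parameter choices and numerical conventions
behind `photomics`, and what the synthetic-cohort tests do and do not
demonstrate about real data.

## Paired differential analysis

Both molecular levels are tested with the same paired linear model: for each
feature, the within-subject difference d_s = x(irradiated, s) − x(control, s)
is summarized by effect = mean(d), t = mean(d)/(sd(d)/√n) with the sample
standard deviation (ddof = 1), and a two-sided p-value from t(n−1).
Expression is analyzed as log2(TPM+1) so the effect is a log2 fold-change;
methylation is analyzed as M values, M = log2(β/(1−β)), so the effect ΔM is
itself a difference of log2 odds and is used wherever a methylation
"fold-change" threshold appears (e.g. the |ΔM| > 0.2 DEMG criterion). This
paired t is a deliberate simplification of count-based (negative binomial)
and moderated-t estimators: it preserves exactly the properties downstream
stages consume — the paired design, effect signs and magnitudes on the log
scales, and BH-FDR control — without dispersion modeling. Zero-variance
differences get a guarded denominator (sd floor 1e-12) and a `degenerate`
flag; an exactly zero effect with zero spread is assigned p = 1.

Benjamini–Hochberg adjustment is implemented as the step-up rule
q_(i) = min_{j≥i} p_(j)·m/j capped at 1, with a stable sort so ties share a
q-value. It is cross-checked in the tests against a brute-force oracle and
against statsmodels.

Direction summaries count a significant CpG as hypomethylated iff its effect
is strictly negative; with no significant CpGs the fractions are NaN, never
zero, so "no evidence" cannot be read as "no hypomethylation".

## Methylation–expression integration

A CpG qualifies for a gene iff the manifest links it to that gene through a
non-Intergenic region class (TSS200, TSS1500, Exon, Enhancer) and it passes
the CpG thresholds; a CpG linked through several classes counts once per
gene. Regional aggregation takes the unweighted mean M over a gene's CpGs of
one class; a CpG linked to two genes contributes to both. The
expression-on-methylation regressions pool both conditions across all
samples and ignore subject pairing — a statistical simplification that
mirrors how such pooled correlation analyses are usually run; the paired
structure inflates the effective correlation of coupled genes, which is
acceptable here because the planted-coupling recovery tests quantify exactly
that behaviour. Slope p-values come from the t-test with n−2 df; BH runs
jointly across all gene × class tests.

Block concordance uses BED-convention intervals (0-based half-open) against
1-based manifest positions: a CpG is inside iff start < position ≤ end.
Blocks without significant CpGs are reported but excluded from the summary
correlation; "concordant" means sign(mean observed effect) equals
sign(reference delta), this package's explicit operationalization of a block
"matching" a previously reported methylation pattern (a magnitude criterion
is deliberately not imposed — acute changes are expected to be smaller than
chronic ones).

## Gene-set enrichment

Per-gene standardization uses the sample standard deviation (ddof = 1), fixed
so the worked examples are exact. The combined score z_S = Σ z_g/√|S| is
standard normal under a per-gene null, making the paired contrast on scores
well calibrated. Zero-variance genes are dropped from sets (warned); empty
sets are omitted. Differential enrichment on all provided sets doubles as
the "enriched terms after irradiation" analysis; no separate
over-representation test is provided.

## MED prediction

Both samples of a subject carry the subject's MED as target, so models learn
dose sensitivity irrespective of exposure status. Outer folds are grouped by
subject — a subject's two samples never straddle a train/test boundary;
otherwise the near-duplicate twin sample would leak subject identity and
inflate out-of-fold accuracy. The penalty path has 100 log-spaced values
from λ_max = max|Xᵀ(y−ȳ)|/n down to 1e-4·λ_max; the inner 5-fold
(also subject-grouped) CV picks the MSE-minimizing penalty, with
standardization refit on every training split (full-data standardization in
`assemble_features` exists only for the final full-data model).
Inner-path coordinate descent runs at loose tolerance (1e-3) since it only
ranks penalties; selected penalties are refit at 1e-6. MAE is the median
absolute error in mJ/cm², reported pooled and per condition.

## Network fusion and phototyping

Only irradiated samples enter fusion: the phototype is defined by the
molecular response to UV. The MED-correlation prefilter (keep the top 10%
of features by |Pearson r| with MED, ties broken lexicographically by
feature id, computed on irradiated samples for consistency with the fusion
input) removes the bulk of response-irrelevant features. Distances are
Euclidean on per-feature z-scores so expression and methylation scales are
commensurate. The affinity kernel is
W(i,j) = exp(−d² / (α·ε_ij)), ε_ij = (μ_i + μ_j + d(i,j))/3 with μ_i the
mean distance of i to its k nearest neighbours (ε floored at 1e-12 so
duplicate samples get affinity 1). Fusion uses the cross-diffusion update
P_v ← S_v · mean_{u≠v}(P_u) · S_vᵀ where P is the full kernel (off-diagonal
rows normalized to sum 1/2, diagonal 1/2) and S the row-stochastic kNN
kernel; each iteration re-normalizes and symmetrizes, and the output is the
symmetrized level average. The normalization variant is fixed here for
reproducibility. Defaults k = 10, t = 20, α = 0.5.

Cluster number: eigen-gap of the symmetric normalized Laplacian,
gap(K) = λ_{K+1} − λ_K over K ∈ [2, 5], smallest K on ties (so a fully
connected uniform network yields K = 2). The rotation-cost criterion is not
implemented. Spectral clustering embeds with the K smallest-eigenvalue
eigenvectors, row-normalizes, and runs k-means with 50 restarts and a fixed
seed; labels are canonicalized by first occurrence. Isolated (zero-degree)
samples are an error naming the sample.

## Pathway predictivity

Gamma is 1 over the number of set genes present in the expression matrix —
the feature space actually used — not the nominal set size. Folds are
stratified by condition; with fewer samples in a class than folds, the fold
count drops to the class size (warned). Features are standardized within
training folds. Heatmap rows are min-max scaled (zero-range rows map to
0.5); z-scaling was rejected because rows have only three entries.

Sample-level folds do not respect subject pairing. On sets without real
condition signal this produces *below*-chance accuracy on paired cohorts
("anti-learning": the held-out twin of a training sample is predicted with
its twin's label, which is always the wrong condition), while genuinely
discriminative sets are unaffected. The null-calibration tests therefore use
unpaired balanced data, where uninformative sets score at 0.5 as expected;
on paired data the below-chance floor only widens the contrast the
predictivity map is meant to show.

## Synthetic cohort generator

The generator is the package's definition of the study conditions, not a
tuning knob. Defaults: 32 subjects, 2,000 genes, 20,000 CpGs, three equally
likely latent phototypes with MED means (100, 150, 200) mJ/cm² and sd 15
(chosen to span the observed range of roughly 100–210 mJ/cm² in Fitzpatrick
type-4 subjects; per-phototype MED distributions are not otherwise
constrained by published numbers), 25% of CpGs and 32.4% of genes carrying
irradiation effects, 65.1% of planted CpG effects negative with the
hypomethylation fraction rising (0.57, 0.63, 0.70, 0.78) from open sea to
islands, 30% of affected genes DEMG-coupled (each with 3–5 regulatory CpGs
whose ΔM sign opposes the gene's log2FC, |ΔM| ≥ 0.45 so they clear the
qualification threshold), 30 MED-predictive features per level (baseline
linear in standardized MED, slopes 0.8–1.2, both conditions), and per
phototype 60 signature genes plus 200 signature CpGs shifted by ±2.0 only in
that phototype's irradiated samples. Signature-CpG signs are drawn with the
same 65.1% hypomethylation bias as the global effects — modeling the
direction bias as a property of the UV response as a whole — so phototype
structure does not dilute the direction summary toward 50%.

Methylation is generated on the latent M scale (Gaussian: per-CpG baseline
U(−4, 4), per-subject effect N(0, 0.5²) shared by the sample pair, residual
N(0, 0.3²)) and mapped to Beta by the logistic β = 2^M/(1+2^M); expression
is generated as Gaussian log2(TPM+1) (baseline U(2, 8), same variance
components) and exponentiated back, clipping TPM at 0. All planted effects
act on these latent scales, where the differential statistics operate.

Annotations derive from the same seeded layout as the matrices: CpGs are
spread over 22 chromosomes with strictly increasing positions (gaps
500–5,000 bp), island relations drawn at EPIC-like proportions
(OpenSea 0.45, Shelf 0.10, Shore 0.20, Island 0.25), non-coupled CpGs carry
0–2 random gene links. Gene sets comprise one shared UV-response pathway
(upregulated affected genes), the three phototype pathways, and null sets
drawn from genes with no planted irradiation response (genuine negative
controls). Reference blocks: concordant blocks are contiguous windows around
planted hypomethylated CpGs, free of other planted signals, with ≥ 3
affected members and |mean planted ΔM| ≥ 0.35; their reference delta is 1.5×
the planted mean (5% jitter, sign preserved) — acute changes smaller in
magnitude than the reference, matching the biology being emulated. The
remaining blocks get random reference deltas as discordant controls.

What the generator does **not** model: read-count noise and library-size
effects, array batch effects and probe cross-reactivity, cell-type
composition shifts, genuine genomic correlation structure between
neighbouring CpGs, dose as a continuous covariate (the 3×0.9-MED protocol is
a binary condition label), and transcript-level quantification (gene-level
values only, so the regional correlations use gene expression rather than
transcript sums). Passing recovery tests therefore demonstrates the
correctness and calibration of the analysis chain under the planted
statistical structure, not performance on real array/sequencing data.

## Problem sizes in the tests

The full default cohort (2,000 × 20,000 features, 32 subjects) is used for
the differential, integration, enrichment and fusion recovery tests and for
the multi-seed acceptance checks (20 seeds for subtype recovery, 10 for the
hypomethylation direction). The MED-model tests run on cohorts with reduced
feature dimensionality (≤ 400 genes / 1,200 CpGs) but unchanged design
constants, because the lasso path over repeated nested CV dominates runtime
while its behaviour is dimension-stable at these scales. Calibration checks
use 500 null simulations (200 features × 16 subjects) for the paired t and
100 null gene sets for the SVM score.

## Known limitations

- The paired t stand-in will differ from count-based or moderated
  estimators in power on real data; thresholds (FDR < 0.05, |log2FC| > 0.5,
  |ΔM| > 0.2) are configurable to compensate.
- Correlation models ignore subject pairing (pooled regression), so their
  p-values are optimistic on paired cohorts.
- The eigen-gap is the only cluster-number criterion; rotation cost is not
  implemented.
- Pathway predictivity uses sample-level folds; see the anti-learning note
  above for the consequences on paired data.
- Fitzpatrick labels in the simulator are a noisy discretization of MED,
  intended only to emulate the poor concordance of the scale; they carry no
  independent signal.
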