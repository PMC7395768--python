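# photomics

Integrative analysis of the acute epidermal response to ultraviolet (UV)
irradiation from paired multi-omics data, plus a synthetic cohort simulator
with full ground-truth bookkeeping for validating every stage.

## The scientific problem

Repeated sub-erythemal UV exposure remodels both the epidermal transcriptome
and the DNA methylome within days. Studies of this response use a paired
design: each subject contributes a control and an irradiated skin sample
(suction blister roofs), profiled for gene expression (TPM) and CpG
methylation (Beta values), together with the subject's minimal erythema dose
(MED, mJ/cm²) — the objective measure of UV sensitivity that the subjective
Fitzpatrick phototype approximates poorly.

`photomics` implements the full analysis chain such a study needs:

1. **Paired differential analysis** — per feature, within-subject differences
   d_s = x(irradiated, s) − x(control, s) tested with a one-sample t
   statistic, t = d̄ / (s_d/√n), two-sided p from t(n−1), Benjamini–Hochberg
   FDR across features. Expression enters as log2(TPM+1); methylation as
   M values, M = log2(β/(1−β)). Direction summaries report the
   hypomethylated share of significant CpGs overall and per CpG-island
   relation (OpenSea → Shelf → Shore → Island).
2. **Methylation–expression coupling** — DEMGs (differentially expressed
   genes, FDR < 0.05 and |log2FC| > 0.5, carrying ≥ 3 differentially
   methylated CpGs with FDR < 0.05 and |ΔM| > 0.2 in regulatory regions);
   per-gene regional mean-M aggregation (Enhancer/TSS1500/TSS200/Exon);
   linear models of expression on regional methylation with joint BH
   correction; concordance of observed methylation change with reference
   genomic blocks (0-based half-open intervals with reported deltas).
3. **Gene-set enrichment** — sample-wise combined z-scores,
   z_S = Σ_{g∈S} z_g / √|S|, followed by the same paired contrast per set.
4. **MED prediction** — subject-grouped 10-fold cross-validated lasso on
   expression, methylation and combined standardized features; penalty per
   fold by inner 5-fold CV over a 100-point log-spaced path from λ_max;
   metrics: median absolute error (mJ/cm²), Pearson r, R².
5. **Molecular phototyping** — per level, keep the 10% of features most
   |r|-correlated with MED (irradiated samples only); scaled-exponential
   affinity W(i,j) = exp(−d²/(α·ε_ij)); similarity network fusion (k = 10,
   t = 20, α = 0.5) by iterative cross-diffusion; eigen-gap estimation of
   the cluster number on the normalized Laplacian; spectral clustering.
6. **Pathway predictivity** — per gene set and phototype, an RBF-kernel SVM
   (γ = 1/|set ∩ expressed|, C = 1) predicting irradiation status, scored by
   5×5-fold repeated stratified CV.

The synthetic generator (`photomics.synthetic`) emulates the statistical
structure of a 32-subject cohort: hypomethylation-biased irradiation effects
(65.1% of planted CpG effects negative, rising from open sea to islands),
DEMG coupling with anti-correlated expression shifts, MED-predictive baseline
features on both levels, and three latent phototypes with subtype-specific
response pathways — every planted effect recorded in a `GroundTruth` ledger.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```bash
$ python examples/02_differential_methylation.py
significant CpGs (q<0.05): 5756 of 20000 (28.8%)
hypomethylated among significant: 64.4%

per island relation (hypomethylated fraction rises toward islands):
                 n_significant  fraction_hypo
island_relation
OpenSea                   2658          0.586
Shelf                      572          0.633
Shore                     1108          0.671
Island                    1418          0.736
```

The recovered 64.4% hypomethylated share matches the 65.1% direction bias
the cohort plants (the shortfall is the expected dilution by sign-symmetric
false discoveries), and the fraction rises monotonically toward CpG islands
as designed. Similarly:

```bash
$ python examples/06_subtyping.py
eigen-gap estimate of cluster number: 3
eigengap per K: {2: 0.0, 3: 0.4124, 4: 0.0437, 5: 0.0134}
cluster sizes: {0: 11, 1: 11, 2: 10}
adjusted Rand index vs planted subtypes: 1.000

median MED per molecular phototype (mJ/cm^2):
subtype
0    160.0
1     99.7
2    208.3
```

The eigen-gap singles out K = 3, spectral clustering recovers the planted
phototypes exactly, and the phototypes order by UV sensitivity.

A thin CLI mirrors the stages (`photomics simulate|run|med|subtype|predictivity`),
e.g. `photomics simulate -o data/ --seed 1` followed by
`photomics run --data-dir data/ -o results/`.

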