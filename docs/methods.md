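# Methods

`castemeth` implements a caste-methylome analysis for pooled whole-genome
bisulfite sequencing (WGBS) of social insects with very sparse CpG
methylation — two reproductive castes sampled as one pooled library per
caste per colony — together with the downstream integration of methylation
with gene-expression results. This note documents the models, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Data model and conventions

Per-CpG counts are held as `(chrom, pos, strand, n_meth, n_total)` rows,
1-based inclusive coordinates (the Bismark convention); BED input is
converted at the boundary. Cytosines on opposite strands are independent
sites — no destranding into CpG dyads, since the upstream extraction is
per-cytosine. Zero-coverage rows survive parsing and are removed only by
the explicit coverage filter, so filtering is observable and testable.

## QC and conversion efficiency

Bisulfite conversion efficiency is estimated from an unmethylated lambda
spike-in as `1 − Σ n_meth / Σ n_total` (one minus the spike's weighted
methylation level). Single-site levels can be corrected for the
non-conversion rate ε as `max(0, (k/n − ε)/(1 − ε))`.

The coverage filter keeps a site iff, in **every** sample,
`min_cov ≤ n_total ≤` that sample's 99.9th-percentile coverage, over the
intersection of all samples' site universes. Defaults: `min_cov = 10`
(reported study wordings disagree between "coverage > 10" and "less than 10
removed"; we keep ≥ 10, i.e. remove < 10), percentile computed **per
sample** with linear interpolation (per-sample outliers reflect
library-specific artifacts). The percentile thresholds are computed once
from the input and recorded in the QC report; re-applying the filter at
those fixed thresholds is exactly idempotent. A rule that re-derived the
percentile from its own output would always find a slightly lower cutoff
on a second pass, so the threshold is filter state, not re-derived.

## Methylation-status calling (MSC)

Per sample, across sites, methylated read counts follow a two-component
mixture:

    P(k | n) = (1 − π) · Binomial(k; n, p0) + π · Comp1(k; n)

with `p0` the non-conversion error rate (fixed at the lambda estimate by
default; freely fitted on request) and `Comp1` a beta-binomial (default)
or point-binomial methylated component. Fitting is per sample, respecting
library-specific error rates. EM details: π initialized from the fraction
of sites with a methylated-read majority, component-1 mean initialized at
0.8 (α=8, β=2); the beta-binomial M-step is a Nelder–Mead refinement from
the current parameters, accepted only if it improves the weighted
objective (a generalized EM step, so the log-likelihood trace is
monotone); convergence at |Δ log L| < 1e−6 or 500 iterations.

Binary calls rank sites by posterior and take the largest call set whose
estimated FDR — the mean of (1 − posterior) over called sites — stays at
or below the target (default 0.05). The non-discovery rate (mean posterior
over uncalled sites) is reported alongside. This marginal-FDR rule
deliberately admits some low-posterior sites once the confident calls have
"earned" FDR budget; the realized false-call rate stays near the target,
and the informative-site filter consequently carries a tail of
sparse-count false calls into the testing stage (see the calibration note
below).

Sites called methylated in at least one sample are "informative"; only
these enter differential testing, which keeps the multiple-testing burden
proportional to the methylated fraction of the genome rather than to its
size.

## Differential methylation

Per informative site, `(n_meth, n_total − n_meth)` across the six
libraries is modelled by binomial logistic regression on caste plus colony
(colony as fixed covariate levels). The caste effect is tested by a
likelihood-ratio test (LRT) against the colony-only model, χ²(1). All
sites share one design matrix, so the per-site fits run through a batched
Fisher-scoring solver (step-halving for monotone likelihood, linear
predictor clipped at ±30); an independent statsmodels GLM serves as the
test oracle and agrees to < 1e−6 in p.

Degenerate sites get an assigned p = 1 with a flag and stay in the tested
universe (keeping BH stable): zero-variability sites; failed likelihood
maximization; and **complete separation on the caste term** — one caste
with no methylated reads at all (or fully methylated) while the other is
off the boundary. In that case the caste coefficient is unbounded and the
χ² approximation is invalid; empirically these sites (mostly sparse
false-positive calls from the MSC stage, e.g. two methylated reads that
land by chance in one caste) otherwise produce badly anticonservative
p-values.

Multiple testing uses Benjamini–Hochberg (the SLIM correction of methylKit
is not reproduced); no overdispersion correction by default. A site is
differentially methylated (DM) at q < 0.05 and an absolute caste-pooled
proportion difference ≥ 0.10. A gene is DM with ≥ 1 DM CpG **and** an
absolute caste weighted-methylation difference ≥ 0.10 across the whole
gene. Caste-level W is the mean of the per-colony-sample W values
(aggregation order: weighted within sample, averaged across colonies);
gene-level W uses the full gene span. Intergenic DM sites are reported
separately with the nearest gene within a 5 kb flank and never count
toward DM genes.

**Calibration.** Type-I behavior of the site test is assessed on null
simulations as the fraction of raw p < 0.05 **among sites where the LRT
was actually computed**; flagged sites carry an assigned p = 1, which is a
convention, not a raw p-value (they do remain in the BH universe). Under
the no-effect conditions below this fraction is ≈ 0.04 — mildly
conservative, as expected for a χ²(1) LRT on six binomial observations.

An optional permutation null shuffles caste labels (or enumerates all
C(6,3) = 20 balanced labelings) and recounts DM sites. With strong shared
colony structure and three colonies the labelings are not exchangeable, so
the distribution is emitted with an explicit warning and should be read
descriptively.

The hyper/hypo direction test is a Pearson goodness-of-fit of the two
direction counts against 50:50, χ²(1).

## Methylation metrics

Weighted methylation W of any unit = Σ n_meth / Σ n_total over its CpGs —
invariant under site subdivision and bounded by the per-site levels. Genes
with W > 0 in ≥ 1 sample are "methylated genes". Gene/caste W is binned
none (W = 0), low (0 < W ≤ 0.2), medium (0.2 < W ≤ 0.7), high (W > 0.7);
boundaries upper-inclusive. Feature-class and linkage-group summaries
report the caste mean of per-sample W with a 95% t-interval across colony
samples.

## Integration with expression

- Expression across methylation bins: Kruskal–Wallis on log(FPKM + 0.01)
  (the offset handles zeros; the study plots log(FPKM) without stating its
  zero handling), with Dunn's rank-based pairwise contrasts
  (tie-corrected, BH-adjusted).
- Expression ~ W × caste with a colony random intercept (statsmodels
  MixedLM); singular or failed fits fall back to OLS with fixed colony
  effects, flagged — the fixed-effect targets are unchanged.
- Gene-set contrasts (DEG vs non-DEG, DEE vs non-DEE, per-gene or
  per-exon): OLS of W on group × caste, reported as a model-comparison
  table (interaction vs main effects; drop-one F tests for the group and
  caste main effects; Res. Df, RSS, Df, sum of squares, F, p).
- Set overlaps: upper-tail hypergeometric P(X ≥ k); the default universe
  is all genes in the expression data, configurable.
- DM-vs-DE relationship: OLS of log2 fold change on the gene's weighted
  methylation difference (needs ≥ 3 genes).
- Sample PCA: centered SVD with a deterministic sign convention (largest
  loading positive); reporting only.

DEG/DEE flags are inputs from upstream count models (or synthetic truth),
never fitted here.

## GO enrichment and orthology

Per GO term annotated to ≥ 1 study gene, upper-tail hypergeometric p
against a configurable background; BH within the run; enriched at
q < 0.05. No GO-graph ancestor propagation. Reciprocal-best-hit orthologs:
e-value ≤ 1e−3 ("minimum e-value" read as a threshold — a floor would be
nonsensical), best hit per query (lowest e-value, ties by bitscore,
unresolved ties discard the query), reciprocal same-partner pairs only,
and any gene matched by more than one distinct partner anywhere in the
best-hit graph is discarded with all its matches. The result is a
one-to-one partial matching; cross-species DM overlap maps one species'
DM genes through it.

## Synthetic data generator

The generator emulates the study design: 6 WGBS libraries (2 castes × 3
colonies), negative-binomial coverage (mean 17.7, size 8, truncated ≥ 1
read), non-conversion ε = 0.0045, a lambda spike, 18 RNA-seq samples
(3 individuals per caste per colony) with negative-binomial gene counts
and Dirichlet-multinomial exon usage, BLAST hit tables with planted
reciprocal pairs and ambiguous matches, and random GO maps.

Methylation structure is **gene-bimodal**, as in real insect genomes: the
methylated-site budget (default 2% of sites, chosen so mixture-model
recovery runs at a realistic methylated fraction; sparse genomes sit
nearer 0.3%, reachable via `frac_methylated_sites`) is spent on fully
methylated genes plus scattered single CpGs. A scattered-uniform layout
was rejected: a gene mixing level-≈1 and level-0 CpGs gets a gene-level W
dominated by coverage-composition noise, which no analysis could undo.
Methylated levels are Beta(8, 2). DM genes are fully methylated genes in
which a quota of sites shifts by ±Δ/2 per caste (default Δ = 0.30; the
base level is restricted to [0.01 + Δ/2, 0.99 − Δ/2] so the true caste gap
is exactly Δ); the hyper-methylated caste is Bernoulli(1/2) **per gene**
and shared by its sites — per-site directions would cancel within a gene
and erase the gene-level signal, while per-gene assignment keeps the
direction test's true null. Colony effects are a shared logit-scale
normal shift (SD 0.5, a free parameter — the study reports the
colony-clustering phenomenon, not a variance) applied to all methylated
sites of a colony's two libraries, which makes samples cluster by colony
in PCA and is exactly what the colony covariate absorbs. Gene size
defaults to 8 CpGs per gene (`sites_per_gene`), the stable quantity in a
scaled-down genome; gene count is derived.

What the generator does **not** emulate: read-level artifacts (mapping
bias, M-bias, duplicates), non-CpG contexts, spatial correlation of
methylation along the genome, methylation–expression coupling (expression
is generated independently unless the test constructs a coupling), and
pool composition effects (a pooled library is one count table; a
three-individual latent-pool mode is not implemented). Passing recovery
tests therefore demonstrate statistical correctness of the pipeline under
the stated generative model, not robustness to alignment artifacts or
model misspecification on real libraries.

## Problem sizes

The shipped benchmarks use 50,000 sites for status-calling recovery,
5,000 sites / 20 DM genes / Δ = 0.30 for the differential pipeline, and
ten no-effect replicates of the same conditions for null calibration —
sizes at which every recovery quantity is stable across seeds while a full
run stays interactive on one CPU.

## Known limitations

- The LRT is asymptotic; at six libraries it is mildly conservative, and
  boundary/sparse sites are handled by flagging rather than by exact or
  penalized (Firth-type) inference.
- No beta-binomial overdispersion in the site test (an optional
  scaled-deviance correction is deliberately out of the default path).
- No region/window DMR detection, no smoothing, no promoter analysis.
- GO enrichment does not propagate term ancestors.
- The caste-level aggregation (mean of colony W) and the full-gene-span
  convention for gene W are documented choices where the field tolerates
  either.
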