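# Methods

## The subtyping model

The pipeline assumes a combined cohort of cholangiocarcinoma (CCA) and
hepatocellular carcinoma (HCC) bulk expression profiles on a common
log2(x+1) scale, with the CCA samples identified a priori (by pathology).
Classification is reference-anchored correlation, not clustering: a sample
is compared (Spearman, average ranks for ties) to fixed per-gene profiles —
the CCA centroid (per-gene median of the CCA samples) and external
lineage references for hepatoblasts, hepatocytes and cholangiocytes.

Before correlating, genes are filtered to those with expression above
`min_expr` (default 1.0 log2 units) in at least `min_expr_fraction`
(default 0.7) of samples, ranked by median absolute deviation, and the top
`top_n_variable` (default 4035) retained; every gene row is then
median-centered. MAD is used as the variability metric because it is
robust to the heavy-tailed expression of marker genes; both the filter and
the metric are configurable.

Two thresholds drive the labels:

* **CCA-Like**: rho to the CCA centroid at or above
  mean(rho over CCA) − sd(rho over CCA), sample standard deviation
  (n−1). The bound is one-sided and inclusive. The rule is meaningful
  because true CCA is transcriptionally heterogeneous: its own spread sets
  how far "CCA-like" may sit from the centroid.
* **Blast-Like**: hepatoblast-centroid rho at or above the 66.67th
  percentile (linear-interpolation quantile) of all non-CCA tumor samples.
  CCA-Like samples count toward the ranking population but are never
  relabeled; tumor-adjacent normals are excluded from the population and
  always keep the label Normal (`tertile_population` switch).

Cross-cohort merging anchors cohort A to cohort B by shifting each shared
gene by the difference of the two cohorts' anchor-class medians, after
which the per-gene anchor medians agree exactly.

## Mutational signatures

Single-base substitutions are collapsed onto the 96 pyrimidine-centred
trinucleotide contexts (purine references are reverse-complemented,
flanks included), in the conventional lexicographic order (C>A, C>G, C>T,
T>A, T>C, T>G x 16 flanking pairs, 5' then 3' in A,C,G,T order). Records
with ambiguous bases or missing context are skipped and reported, and
zero-SNV samples are retained with zero counts but excluded from cosine
operations (their profile is undefined).

De novo extraction factorizes the per-sample *frequency* matrix (96 x
samples) — frequencies rather than counts so hypermutators do not dominate
the loss; `use_frequencies=False` restores count factorization. The
factorization is Frobenius-loss multiplicative-update NMF: 20 random
restarts, 2000 maximum iterations, relative-improvement tolerance 1e-8,
best restart by reconstruction error. The error trajectory is recorded at
every iteration and verified non-increasing (up to float noise on the
initial-error scale, 1e-10 relative); a violation raises. Signatures are
column-normalized to unit sum with exposures rescaled compensatingly and
ordered by total exposure. k is a parameter with no automatic model
selection. Catalog matching is plain cosine similarity with motif rows
aligned by label, never by position.

## Copy number

Class comparison operates on two representations: continuous values (class
means, pairwise difference tracks ordered by genomic coordinate, per-feature
Welch t-tests at alpha = 0.05) and discretized GISTIC-style calls in
{−2,−1,0,1,2} (segment-wise two-sided Fisher exact tests on class x altered
tables, Benjamini–Hochberg over all tested segments, significant at
FDR < 0.05). "Altered" is direction-specific (loss: call ≤ −1; gain:
call ≥ +1) with `any` (call ≠ 0) as the default for landscape-wide scans,
since a class-specific event may be a gain in one comparison and a loss in
the other. The segment test is a deliberate simplification of dedicated
segment-comparison tools: the statistical core (per-segment Fisher + BH) is
implemented; probe-level segmentation and segment merging are not, so
significant-segment *counts* are defined per feature of the input table.

## Nearest-centroid classifier

Training computes, per gene and class, a moderated class-vs-rest score
(class mean − overall mean) / (pooled within-class SD + s0), with s0 the
median pooled SD across genes — the stabilizer keeps near-zero-variance
genes from producing unbounded scores. Genes are selected greedily from
the global score ranking, at most one class per gene, an even split of the
configured total (default 150) across classes, ties broken by gene id.
Centroids are class means of the centered training data over the selected
union. Prediction median-centers the new cohort on itself, requires at
least 50% of classifier genes, and assigns each sample the class with the
highest Spearman correlation to its centroid (ties to the first class in
name order, logged). Correlation-based prediction, rather than a
distance rule, is what makes the classifier portable across platforms: it
is invariant to monotone per-sample transforms and, combined with
per-cohort centering, to global per-gene shifts.

## Survival

Follow-up is administratively censored at a five-year horizon (1826 days =
5 x 365.25 rounded; times strictly beyond the horizon become censored at
the horizon, a time exactly at it keeps its event). Curves are
Kaplan–Meier product-limit estimates with the first-crossing (S ≤ 0.5)
median rule; group comparison is the k-group log-rank test (df = k−1); and
hazard ratios come from Cox proportional-hazards models with Efron tie
handling, categorical covariates expanded against an explicit referent
(HCC for the class label). The multivariate model is an explicit covariate
list chosen from univariate-significant covariates plus the class labels,
never a silent automated selection. KM, log-rank and Cox are delegated to
`lifelines`; the test suite checks them against hand-computed product
limits and the analytic score-test/log-rank identity.

## The synthetic cohort generator

The generator plants the structure the analysis assumes, so recovery is
measurable:

* **Expression.** Three latent log2 programs (hepatocyte, cholangiocyte,
  hepatoblast): a shared baseline Uniform(2, 8) per gene, a
  transcriptome-wide per-program deviation N(0, `program_sd`=3.0), and a
  `marker_effect`=4.0 boost on 150 dedicated marker genes per program, out
  of 2000 genes. A sample is a convex mixture of the programs plus
  N(0, `noise_sd`=0.5) per gene. Default class weights
  (hepatocyte, cholangiocyte, hepatoblast): CCA and CCA-Like
  (0.15, 0.55, 0.30), Blast-Like (0.25, 0.10, 0.65), HCC
  (0.80, 0.10, 0.10); per-sample weight jitter SD 0.05 for CCA and 0.015
  for the HCC-derived classes — true CCA is the heterogeneous class, which
  is exactly what gives the mean − 1 SD rule its meaning. With these
  defaults the CCA self-correlation distribution sits near mean 0.73,
  SD 0.09, the regime in which the rule is known to operate on real
  cohorts. Default cohort: n=40 per tumor class, normals optional.
* **Mutations.** Per-sample SNV counts are lognormal (log-mean 4.4 ≈ 80
  mutations, log-SD 0.6, exome-like). Motifs are drawn from a per-sample
  Dirichlet mixture of three planted signatures, each 90% concentrated on
  one substitution block (C>T, T>A, C>A) over a 10% uniform background
  (pairwise cosine < 0.1). Class exposure profiles make the biliary-type
  classes C>T-dominated and the hepatocyte-type classes T>A / C>A-heavy.
  Half of Blast-Like tumors (configurable) receive a TP53 p.R249S record
  and a 0.3 exposure tilt toward the aflatoxin-like C>A signature, giving
  the R249S association test real signal. Contexts are written inline, so
  no reference genome is ever needed.
* **Copy number.** Gene-level baseline N(0, 0.1) with four planted
  arm-scale events (a 3p loss at penetrance 0.80/0.45/0.12/0.12 for
  CCA/CCA-Like/Blast-Like/HCC — the BAP1-region pattern — plus 8q, 6p and
  1q gains). Calls discretize at ±0.3 → ±1 and ±1.0 → ±2. The orchestrated
  bundle couples expression to continuous copy number at 1.0 log2 units
  per CN unit, so dosage correlation exists at event genes.
* **Survival.** Exponential times (Weibull shape configurable), baseline
  median 880 days, hazard ratios 1.5/1.7/2.0/1.0 for
  CCA/CCA-Like/Blast-Like/HCC. Each sample is independently censored with
  probability `censoring_rate`=0.3, the censored time Uniform(0, T) —
  this controls the censored fraction exactly, at the cost of censoring
  that is not independent of T; the null-calibration tests show the
  log-rank test keeps its level under this scheme.

What the generator does *not* emulate: batch and purity effects,
compositional (tumor/stroma/immune) deconvolution structure, mutation rate
covariates along the genome, focal versus arm-level CN architecture, or
informative censoring. Passing recovery tests therefore demonstrates the
statistical machinery is correct under the planted model, not that the
thresholds are optimal for any particular real cohort.

## Numerical and design choices

* Thresholds for "highly/variably expressed" are not canonical; defaults
  (1.0 log2 units, 70%, top 4035 by MAD) are configurable, and requesting
  more genes than survive keeps them all with a warning.
* Duplicate gene symbols collapse to the row with the highest mean
  expression; missing expression values are an error, never imputed.
* All coordinates are 1-based inclusive (MAF/SEG convention).
* Boundary rules are inclusive (≥) at both classification thresholds and
  at the immune high/low median split.
* Welch (unequal-variance) t-tests and two-sided p-values throughout.
* Catalog columns off unit-sum by more than 1e-6 but less than 0.5 are
  renormalized with a warning; larger deviations are an error.
* Module scores are medians of median-centered expression over the set
  (configurable to mean); the immune high/low split is at the cohort
  median of the per-sample overall scores.
* Problem sizes in the validation suite — n=40 per class for label
  recovery, 200 samples x ~500 mutations for signature recovery, 100–200
  replicates for calibration — were chosen as the smallest cohorts at
  which the corresponding real-data analyses are typically attempted, so
  the suite exercises the regime the method is meant for while staying
  fast enough to run on every change.

## Known limitations

* The segment Fisher test treats every input feature as a segment; it does
  not reproduce probe-level segmentation, so significant-segment counts
  are not comparable across tables with different feature resolutions.
* The NMF has no model-selection criterion for k; the caller must choose.
* Cox models assume proportional hazards; no diagnostic is built in.
* The classifier's even gene split across classes is a convention, not an
  optimum; unequal class difficulty is not accounted for.
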