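# Methods

This note documents the statistical models implemented in `cardioqtl`, the
design of the synthetic cohort they are exercised on, the numerical choices
that matter, and what the validation studies do and do not establish.

## The combined cis-eQTL model

Expression of each feature (gene TPM or isoform usage, inverse-normal
transformed) is modeled with a linear mixed model

    Y_i = β_j X_ij + Σ_m γ_m PC_im + Σ_n γ_n F_in + Σ_p γ_p C_ip + u_i + ε_ij

where `X_ij` is the standardized dosage of cis variant `j` (all variants
within ±500 kb of the feature's gene body are tested), `PC` the genotype
principal components, `F` latent expression factors, `C` technical
covariates, and `u ~ N(0, σ²_g K)` a random effect with the kinship matrix
`K` as covariance, absorbing relatedness and repeated-donor structure;
`ε ~ N(0, σ²_e I)`.

Implementation: one eigendecomposition of `K` per kinship matrix rotates the
model into independent observations with variances `σ²_g s_i + σ²_e`.
Variance components are estimated by REML (profiled over the variance
fraction `h²` with a grid + bounded Brent search) **once per feature under
the covariates-only null** and the resulting weights are reused for every
cis variant of that feature — the approximation family used by the standard
scan tools, and the reason the scan is fast enough to run thousands of
features. Per variant, the test is a Wald t-test in the whitened space
(df = n − p − 1), with the residual scale re-estimated per variant.
Conditional scans re-estimate the variance components under the expanded
null that includes prior lead dosages.

Because genotypes are standardized inside the scan, estimated betas are in
(expression SD per genotype SD) units and directly comparable with the
planted effects of the synthetic cohort.

### Multiple testing (two-step)

1. **Gene level.** The minimum cis p-value is corrected by the effective
   number of tests `M_eff`, computed from the eigenvalues of the cis
   genotype correlation matrix in windows of 200 variants: per window, the
   smallest m whose top-m eigenvalues capture ≥ 99% of total variance;
   windows are summed and corrected p = min(1, p_min · M_eff). A
   permutation study (tests) confirms M_eff tracks the permutation-implied
   effective test count within ~25% and the corrected p matches the
   permutation-exact gene-level α in the significance regime.
2. **Genome level.** Benjamini–Hochberg across all features' corrected lead
   p-values; q < 0.05 is significant. Conditional signals are judged
   against the corrected-p cutoff implied by the primary family (the
   largest corrected p accepted at q < 0.05), up to five conditional
   signals per feature; candidate leads with r² > 0.95 to a prior lead are
   skipped for the next-best variant.

## Fine-mapping and colocalization

Per-variant approximate Bayes factors use the normal prior b ~ N(0, W),
W = 0.15² by default (the quantitative-trait default of the standard coloc
implementation; exposed in `ABFConfig`):

    log ABF = ½ [ log(1 − r) + r z² ],   r = W / (se² + W),  z = β̂/se

Single-signal fine-mapping assumes one causal variant with a flat prior, so
PPA is the softmax of log-ABFs; the 99% credible set is the shortest
descending-PPA prefix with cumulative mass strictly > 0.99 (ties broken by
position then variant id; a 1e-12 tolerance on the boundary keeps the
strictly-greater rule faithful to exact arithmetic).

Colocalization of two traits over one shared, ordered variant list computes
the five standard hypothesis sums in log space (H3 via a stable
log-difference), with priors p1 = p2 = 1e-4, p12 = 1e-5. Labels:
PP-H4 > 0.8 → colocalized, PP-H3 > 0.8 → distinct, otherwise not resolved.
Per-variant posteriors under H4 (`∝ exp(lABF1 + lABF2)`) provide the
coloc-conditional credible sets used for GWAS fine-mapping. For features
with several independent signals, every (signal, signal) pair is tested and
the maximum-PP-H4 pair is reported, with conditional signals contributing
their conditioned summary statistics.

All five posteriors are verified against brute-force enumeration over the
(n+1)² causal-configuration pairs to 1e-10, and log-ABFs against numerical
quadrature of the marginal-likelihood ratio to 1e-8; the pipeline is stable
to |z| = 40 (log-space throughout).

## Spatiotemporal classification

For each significant signal's lead variant and each of 16 contexts (2
stages, 2 organs, 4 tissues as binary indicators; 8 cell types as
deconvoluted fractions), the same LMM gains a context main effect and a
genotype×context interaction; the interaction Wald p is
Bonferroni-corrected per context (family = signals tested for that
context). Significant interactions trigger subset refits — tested context
vs all other samples for binary contexts; top vs bottom quartile of the
cell fraction for cell types (quartile ties resolved by a stable sort on
sample id) — with BH across all (signal, context, subset) refits in the
run, and the four-scenario table:

| set A (context) | set B (rest/bottom) | label |
|---|---|---|
| significant | not | specific |
| not | significant | not_classified |
| significant, \|β_A\| > \|β_B\| | significant | associated |
| significant | significant, \|β_B\| ≥ \|β_A\| | not_classified |

Subsets below 30 samples refuse classification (the sources do not state a
minimum; 30 prevents degenerate refits). A signal may carry labels in
several contexts — exclusivity is never forced. Non-significant
interactions are labelled shared.

## GWAS integration

Signal/trait pairs are testable when the feature lies within 500 kb of a
genome-wide significant GWAS variant (p < 5e-8, strict). Colocalizations
with PP-H4 > 0.8 are clustered into independent GWAS loci: nodes are
colocalizations, edges join pairs sharing a lead SNP or with leads in high
LD (D′ > 0.8), and communities come from seeded Louvain modularity
maximization (resolution 1.0). D′ and r² are counted from phased haplotypes
when the panel carries them, otherwise estimated by the two-locus EM
algorithm on unphased dosages. Per cluster, the smallest member credible
set is selected (ties: highest lead PPA, then lexicographic id) and
compared with GWAS-only fine-mapping by paired t-tests on set size and lead
PPA. Fine-mapped leads are classified against a catalog of same-trait index
SNPs: index_match / high LD (r² > 0.8) / low-to-moderate LD
(0.2 ≤ r² ≤ 0.8, upper bound inclusive as printed in the source bands;
high-LD takes strict precedence) / novel.

Context enrichment per trait uses Fisher's exact test of {context-
associated} × {PP-H4 > t} over t = 0, 0.05, …, 0.95, BH across all tests
per trait; a context is flagged for a trait when adjusted p < 0.1 at
t = 0.8. Degenerate margins report the OR as NA alongside a
Haldane-corrected estimate.

## Enrichment statistics

Fine-mapped variants (PPA > 0.01) are annotated against interval tables
(internally 0-based half-open; variant positions 1-based). Promoters are
the 2000 bp upstream of the TSS, strand-aware; splice windows extend 5 nt
(short) or 100 bp (long) into the intron from the exon boundary — the
direction is a documented choice, configurable, since "upstream of the
splice site" is ambiguous; exon/intron boundary ties resolve by a fixed
precedence list with exon over intron. Gene-vs-isoform and the antisense
contrasts are per-class Fisher tests with BH; CIs on log2 OR use the
normal approximation on the Haldane-corrected table (standing in for the
conditional-MLE interval R's fisher.test reports — the point estimates and
p-values are exact). Antisense pairs are detected by the "GENE" /
"GENE-AS1" symbol convention, with an explicit pair table as the robust
override. Multigenic sharing connects signals of different genes within
500 kb at PP-H4 > 0.8 and takes connected components; the context
association of sharing is measured both by OLS of the binary context label
on the sharing-gene count and by a 100-permutation Z test of label
co-occurrence within colocalizing pairs. The chromatin-state analysis
regresses the binary state overlap on SNP PPA per state with BH.

## The synthetic cohort

The generator emulates the study design at desk scale: 400 samples from 330
donors by default (the published 966×491 scale is a config choice), split
18.6% fetal-like iPSC-CVPC / 81.4% adult with adult tissues in the
published 227:125:196:238 proportions; organs derive from tissues; cell
fractions are Dirichlet draws with tissue-group-specific concentrations
(cardiac-muscle-rich heart and iPSC-CVPC, smooth-muscle-rich arteria).
Donors may contribute several samples; a configurable fraction of donors
form first-degree pairs that share one transmitted haplotype at every locus
(kinship coefficient exactly 0.25 in expectation — block-explicit
relatedness keeps pedigree assertions sharp).

Haplotypes come from a Gaussian-copula first-order chain: a latent AR(1)
process with autocorrelation `ld_rho` (default 0.9) thresholded at each
variant's allele-frequency quantile, so marginal frequencies are exact and
LD decays geometrically. Dosages are encoded {0, 0.5, 1}. Loci cycle over
22 autosomes with 250 kb gaps so neighbouring genes see each other's 500 kb
windows (background pairs for the sharing analyses) while their haplotypes
stay independent.

Expression: model-scale `Y = covariates + latent factors + polygenic
(h² = 0.3 on the pedigree relationship) + genetic effect + noise`, with
effects in SD units on standardized dosage; shared labels plant a main
effect (grid 0.5/0.8/1.0), specific labels an interaction only, associated
labels both with the same sign (in-context slope = effect, out-of-context
= half). Cell-type interactions are scaled ×2.5 to offset attenuation by
fractions < 1. TPM is a monotone exponential map of Y; the model-scale
matrix is also exposed because rank-based normalization recovers Y only up
to scale, and oracle tests about the linear model itself (planted-beta
coverage) need the native scale. Isoform usage is logistic-normal on the
per-gene simplex; planted usage-eQTLs act in opposite directions on two
isoforms (cancelling at gene level), and sit at the gene's own causal
variant or at an independent low-LD variant in a configurable split
(default 50/50), so eIsoform/eGene colocalization produces both shared and
distinct classes. GWAS summary statistics come from marginal OLS in a
freshly simulated unrelated cohort (default n = 10,000) sharing the panel's
LD law, with H4 loci reusing the eQTL causal variant and H3 loci a distinct
variant with r² < 0.2 (locus construction fails loudly if none exists); at
most one GWAS relation per locus keeps each trait's table one-row-per-
variant. All randomness flows from one seed sequence with deterministically
spawned sub-streams per component and per gene; identical configs give
byte-identical written artifacts.

What the generator does **not** emulate: real LD panels (no recombination
hotspots or population admixture), sequence-level effects, empirical TPM
dispersion, deconvolution error in cell fractions, or any coupling between
GWAS relations and context labels (so a null context-trait enrichment is
the calibrated answer on default cohorts). Passing tests therefore
establish the statistical machinery — calibration, error control,
planted-truth recovery under the stated generative assumptions — not
performance on real cardiac data.

## Validation studies and problem sizes

The studies in `cardioqtl.validation` (run by `scripts/acceptance.py` and
the acceptance tests) use these conditions, chosen once as desk-scale
analogues of the study design:

- **Coloc enumeration**: 100 random loci of ≤ 10 variants; agreement to
  1e-10. **ABF quadrature**: 1000 (β, se, W) points; 1e-8.
- **Fine-mapping calibration**: 500 loci, n = 400, β = 0.5, 60 variants at
  ld_rho 0.9; 99% credible-set coverage of the planted variant.
- **LMM calibration**: 400 samples from 150 donors (repeated donors plus
  30% of donors in first-degree pairs), polygenic h² = 0.6; 2000 null
  tests and 300 planted β = 0.5 effects. Kinship is estimated on
  background loci and variants tested on held-out loci (a LOCO-style
  split): estimating the GRM from the same small high-LD panel being
  tested produced a mild type-I inflation traceable to estimator noise
  (the true pedigree matrix calibrates exactly), and the leave-out split
  is the standard remedy.
- **Two-step FDR**: 20 replicates × 500 features (80% null, planted
  β = 0.6, 30-variant loci, n = 400 with relatedness).
- **Classifier recovery**: 25 planted specific signals per context kind
  (stage / tissue / cell type, β₃ = 0.8) plus 60 shared signals on one
  cohort; sensitivity counts strict "specific" calls.
- **GWAS integration**: 100 H4 + 100 H3 loci, eQTL β = 0.8 (n = 400),
  GWAS β = 0.09 (n = 10,000, |z| ≈ 9) at ld_rho = 0.995 over 80 variants —
  dense LD keeps GWAS-only credible sets genuinely ambiguous so the
  coloc-vs-GWAS-only set-size contrast is informative rather than
  degenerate at 1 SNP each.
- **Enrichment machinery**: 200 random 2×2 tables against the
  hypergeometric tail-sum oracle; 100 replicates of planted 3× enrichment
  (colocalization rates 0.6 vs 0.2 over 200 signals, 2 null contexts).
- **Determinism**: the full simulate → write → preprocess → map pipeline
  twice on one config; SHA-256 over all artifacts.

## Numerical choices and edge cases

- Rank-to-normal mapping uses (rank − 0.5)/n with average ranks for ties,
  followed by exact standardization (mean 0, sd 1 to 1e-6); idempotent;
  constant features become zeros with a warning.
- HWE is the 1-df χ² test; "MAF > 1% in both studies" generalizes to
  per-stratum MAF when a cohort column is declared.
- Kinship is the standardized-dosage GRM halved to kinship-coefficient
  scale (diagonal ≈ 0.5, full sibs ≈ 0.25, matching the KING convention);
  the LMM absorbs the scale into σ²_g. Eigenvalues are clipped at 0.
- Genotype PCs fix signs by making each component's largest-magnitude
  loading positive; k = 0 yields an empty covariate block.
- Latent expression factors default to top expression PCs — a stand-in
  chosen because the factor model itself is interchangeable here while the
  count-selection sweep (decile-stratified 200-gene sample, argmax of
  detected eQTLs, ties toward fewer factors) is reproduced in full.
- Collinear covariate columns are dropped with a warning (QR with a
  relative tolerance); non-PSD kinship is clipped with a warning;
  zero-variance genotypes are skipped (NaN statistics).
- Fisher CIs: normal approximation on the Haldane-corrected table.

## Known limitations

- Single-causal-variant fine-mapping only; conditional signals mitigate
  but do not replace multi-causal methods.
- The per-feature REML-once approximation slightly misstates per-variant
  variances when a variant explains substantial variance; Wald tests with
  null-model weights are standard but not exact.
- The symbol-suffix antisense rule is fragile by construction (an explicit
  pair table overrides it), and at desk scale (8 pairs) the antisense
  enrichment is directionally correct but underpowered.
- Binary-context refits compare one context against all other samples;
  nested contexts (a tissue inside an organ) therefore share information
  and a signal may legitimately carry several labels.
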