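# cardioqtl

Spatiotemporal cis-eQTL mapping for cardiac transcriptomes: kinship-aware
linear mixed models for gene- and isoform-level associations, Bayesian
fine-mapping and colocalization, genotype-by-context interaction
classification (developmental stage, organ, tissue, cell type), GWAS
integration with credible-set fine-mapping, and the accompanying enrichment
statistics — exercised end-to-end on a synthetic cohort generator that
plants known truth, so every stage of the pipeline is testable without any
restricted data access.

## The problem

Most variants implicated by cardiac GWAS are regulatory, and a regulatory
variant may act only in one developmental stage, tissue or cell type.
Detecting that requires (i) an eQTL scan across a heterogeneous collection
of heart samples that properly handles repeated donors and genetic
relatedness, (ii) a test of whether each association is modulated by the
sample's spatiotemporal context, and (iii) a way to connect eQTL signals to
GWAS signals at the resolution of individual causal variants. This package
implements that full chain for cohorts resembling a combined fetal-like
(iPSC-derived cardiovascular progenitor) + adult (atrium, ventricle, aorta,
coronary artery) design with deconvoluted fractions for eight cardiac cell
types.

## Models at the core

**Combined scan.** For feature expression Y (inverse-normal transformed)
and cis variant j within ±500 kb:

    Y_i = β_j X_ij + Σ_m γ_m PC_im + Σ_n γ_n F_in + Σ_p γ_p C_ip + u_i + ε_ij,
    u ~ N(0, σ²_g K),  ε ~ N(0, σ²_e I)

with kinship K as the random-effect covariance. Significance uses a
two-step correction: per feature, min-p × the effective number of tests
from the eigenvalues of the cis LD matrix; genome-wide, Benjamini–Hochberg
at q < 0.05. Up to five conditional signals per feature are found by
stepwise conditioning on lead dosages.

**Fine-mapping / colocalization.** Per-variant Wakefield approximate Bayes
factors, log ABF = ½[log(1−r) + r z²] with r = W/(se²+W); single-causal
PPAs; 99% credible sets; five-hypothesis colocalization (PP-H0…PP-H4) for
any pair of summary-statistic vectors (eIsoform/eGene, eGene/eGene,
eQTL/GWAS), with per-variant H4 posteriors providing coloc-conditional
credible sets for GWAS loci.

**Context classification.** Per significant signal and context, the LMM
gains a genotype×context interaction (Bonferroni per context); significant
interactions are refit in the context subset vs the rest (top vs bottom
quartile for cell fractions) and labelled shared / specific / associated /
not-classified by the four-scenario decision table.

See `docs/methods.md` for the full model descriptions, numerical choices
and the synthetic cohort's generative model.

## Worked example

The analysis drivers run the whole study on a 400-sample desk-scale cohort
(seed 42) and write tables under `results/`:

```bash
cd analysis
python 01_simulate_cohort.py
python 02_preprocess.py
python 03_map_eqtls.py
python 04_finemap_and_coloc.py
python 05_spatiotemporal_contexts.py
python 06_gwas_integration.py
python 07_enrichment.py
```

`01` prints the cohort composition — 400 samples from 330 donors (75
fetal-like iPSC-CVPC, 325 adult), 24,000 variants in 120 loci, planted
labels `{'shared': 51, 'null': 49, 'specific': 14, 'associated': 6}` and
GWAS relations `{'H4': 11, 'H3': 7}`. `03` then reports

```
genes: 64 e-features, 65 signals (1 conditional)
gene-level recovery vs planted truth: 64 true, 0 false, 7 missed
median lead-to-causal r2: 1.000 over 64 signals
```

i.e. every planted eQTL that is detectable in the combined scan is found
with no false eGenes, and lead variants tag the planted causal variants
(misses are effects confined to small contexts, which only the interaction
analysis can see). `04` labels eIsoform/eGene pairs by colocalization
(9 colocalized, 27 distinct — all 27 belonging to genes with a planted
independent usage-eQTL, 40 with no eGene). `06` colocalizes signals with
the simulated GWAS trait, clusters them into 9 independent loci, selects
credible sets and classifies their leads against a synthetic catalog
(5 index matches, 4 novel). `07` runs the multigenic, antisense and
chromatin-state enrichments; the chromatin-state regression recovers the
planted enhancer enrichment (slope 0.51, p ≈ 1e-9) with a null quiescent
state.

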