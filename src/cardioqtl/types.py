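"""Shared in-memory containers for the eQTL pipeline.

Conventions used throughout the package:

* dosage matrices are (n_samples, n_variants) with values in {0, 0.5, 1}
  (alt-allele count / 2); NaN marks missing calls before filtering;
* variant tables are pandas DataFrames with at least
  ``id, chrom, pos, ref, alt`` (pos is 1-based, as in VCF);
* kinship matrices are kinship coefficients (standardized GRM / 2,
  diagonal ~ 0.5) — the LMM absorbs the scale into its variance component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenotypePanel:
    """Encoded variant panel plus per-variant metadata and side products."""

    variants: pd.DataFrame          # id, chrom, pos, ref, alt [, maf, hwe_p, call_rate]
    dosages: np.ndarray             # (n_samples, n_variants), values {0, 0.5, 1} or NaN
    samples: list[str]
    kinship: np.ndarray | None = None       # (n_samples, n_samples)
    genotype_pcs: np.ndarray | None = None  # (n_samples, k)
    haplotypes: np.ndarray | None = None    # (2 * n_individuals, n_variants) 0/1, optional
    sample_to_individual: np.ndarray | None = None  # index into individual axis

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, mask: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypePanel(
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
            samples=self.samples,
            kinship=self.kinship,
            genotype_pcs=self.genotype_pcs,
            haplotypes=self.haplotypes[:, idx] if self.haplotypes is not None else None,
            sample_to_individual=self.sample_to_individual,
        )

    def subset_samples(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypePanel(
            variants=self.variants,
            dosages=self.dosages[idx, :],
            samples=[self.samples[i] for i in idx],
            kinship=self.kinship[np.ix_(idx, idx)] if self.kinship is not None else None,
            genotype_pcs=self.genotype_pcs[idx] if self.genotype_pcs is not None else None,
            haplotypes=self.haplotypes,
            sample_to_individual=(
                self.sample_to_individual[idx] if self.sample_to_individual is not None else None
            ),
        )


@dataclass
class ExpressionMatrix:
    """Gene- or isoform-level expression with feature coordinates.

    ``state`` tracks normalization: 'tpm' (raw positive scale), 'usage'
    (per-gene simplex values), or 'inverse_normal'. Isoform matrices in
    'tpm' state may carry a parallel ``usage`` array (same shape as
    ``values``) so the joint TPM/usage filter can be applied.
    """

    features: pd.DataFrame          # id, gene_id, chrom, start, end, strand, level
    samples: list[str]
    values: np.ndarray              # (n_features, n_samples)
    state: str = "tpm"
    usage: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if self.state not in ("tpm", "usage", "inverse_normal"):
            raise ValueError(f"unknown state {self.state!r}")

    @property
    def n_features(self) -> int:
        return len(self.features)

    def subset_features(self, mask: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            features=self.features.iloc[idx].reset_index(drop=True),
            samples=self.samples,
            values=self.values[idx],
            state=self.state,
            usage=self.usage[idx] if self.usage is not None else None,
        )

    def feature_values(self, feature_id: str) -> np.ndarray:
        row = self.features.index[self.features["id"] == feature_id]
        if len(row) != 1:
            raise KeyError(feature_id)
        return self.values[row[0]]


@dataclass
class ScanResult:
    """Per-variant association statistics for one feature over its cis window."""

    variant_ids: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray

    @property
    def lead_index(self) -> int:
        p = np.where(np.isnan(self.p), np.inf, self.p)
        return int(np.argmin(p))


@dataclass
class EqtlSignal:
    """One independent eQTL association (primary or conditional)."""

    feature_id: str
    level: str                      # 'gene' | 'isoform'
    signal_rank: int                # 0 = primary, 1..5 conditional
    lead_id: str
    scan: ScanResult
    corrected_p: float              # gene-level (effective-tests) corrected p of the lead
    q: float = np.nan               # genome-wide BH q
    conditioned_on: tuple[str, ...] = ()

    @property
    def lead_beta(self) -> float:
        return float(self.scan.beta[self.scan.lead_index])


@dataclass
class CredibleSet:
    """99% credible set: shortest descending-PPA prefix with mass > 0.99."""

    variant_ids: list[str]
    ppas: np.ndarray
    cumulative: np.ndarray

    @property
    def lead(self) -> str:
        return self.variant_ids[0]

    @property
    def lead_ppa(self) -> float:
        return float(self.ppas[0])

    @property
    def size(self) -> int:
        return len(self.variant_ids)


@dataclass
class ColocResult:
    """Five-hypothesis colocalization posterior for one trait pair."""

    pp: np.ndarray                  # [PP-H0, ..., PP-H4]
    n_variants: int
    label: str                      # 'colocalized' | 'distinct' | 'not_resolved'
    variant_ids: np.ndarray | None = None
    h4_ppa: np.ndarray | None = None        # per-variant posterior under H4
    signal_pair: tuple | None = None        # provenance from best_pair_coloc

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])

    @property
    def pp_h3(self) -> float:
        return float(self.pp[3])

    @property
    def lead_shared_variant(self) -> str | None:
        if self.h4_ppa is None or self.variant_ids is None or len(self.variant_ids) == 0:
            return None
        return str(self.variant_ids[int(np.argmax(self.h4_ppa))])


@dataclass
class InteractionResult:
    """Interaction-LMM statistics and subset refits for one signal x context."""

    signal_id: str
    context: str
    context_kind: str
    beta1: float
    beta2: float
    beta3: float
    se3: float
    p_interaction: float
    p_bonferroni: float = np.nan
    beta_a: float = np.nan
    q_a: float = np.nan
    beta_b: float = np.nan
    q_b: float = np.nan
    classification: str = "not_classified"


@dataclass
class ContextDefinition:
    """A stage/organ/tissue membership indicator or a cell-type fraction."""

    name: str
    kind: str                       # 'stage' | 'organ' | 'tissue' | 'cell_type'
    values: np.ndarray              # per-sample indicator (binary kinds) or fraction

    def __post_init__(self) -> None:
        if self.kind not in ("stage", "organ", "tissue", "cell_type"):
            raise ValueError(f"unknown context kind {self.kind!r}")

    @property
    def is_binary(self) -> bool:
        return self.kind != "cell_type"


DEFAULT_CONTEXT_NAMES: dict[str, list[str]] = {
    "stage": ["iPSC-CVPC", "adult"],
    "organ": ["arteria", "heart"],
    "tissue": ["atrium", "ventricle", "aorta", "coronary_artery"],
    "cell_type": [
        "cardiac_muscle",
        "smooth_muscle",
        "endothelial",
        "fibroblast",
        "immune",
        "cardiac_neuron",
        "endocardial",
        "myofibroblast",
    ],
}

TISSUE_TO_ORGAN = {
    "aorta": "arteria",
    "coronary_artery": "arteria",
    "atrium": "heart",
    "ventricle": "heart",
}


@dataclass
class GWASSummaryStats:
    """Per-variant GWAS summary statistics for one trait."""

    trait: str
    table: pd.DataFrame             # chrom, pos, ref, alt, id, beta, se, pval, af
    n: int = 0

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "ref", "alt", "id", "beta", "se", "pval", "af"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"GWAS table missing columns: {sorted(missing)}")
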