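"""Configuration for the synthetic spatiotemporal cardiac cohort.

Defaults emulate the study design at desk scale: 966 samples from 491
donors across two stages (fetal-like iPSC-CVPC and adult), four adult
tissues in the published proportions (227 aorta / 125 coronary artery /
196 atrium / 238 ventricle), eight deconvoluted cell types, LD-structured
genotypes with explicit first-degree-relative blocks, and planted
shared / context-specific / context-associated / null eQTLs for genes and
isoforms plus GWAS signals that colocalize (same causal variant), conflict
(distinct causal variant) or are absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ..types import DEFAULT_CONTEXT_NAMES

STAGE_SAMPLE_FRACTION = 180 / 966          # iPSC-CVPC share of samples
ADULT_TISSUE_WEIGHTS = {                   # of the adult samples
    "aorta": 227 / 786,
    "coronary_artery": 125 / 786,
    "atrium": 196 / 786,
    "ventricle": 238 / 786,
}
STAGE_DONOR_FRACTION = 139 / 491           # iPSC-CVPC share of donors

LABELS = ("shared", "specific", "associated", "null")
GWAS_RELATIONS = ("H4", "H3", "none")


@dataclass
class SimulationConfig:
    n_samples: int = 400
    n_individuals: int = 360
    n_genes: int = 200
    isoforms_per_gene: tuple[int, int] = (2, 4)
    n_variants_per_locus: int = 300
    ld_rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    contexts: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CONTEXT_NAMES.items()}
    )
    effect_grid: tuple[float, ...] = (0.5, 0.8, 1.0)
    fraction_specific: float = 0.15
    fraction_associated: float = 0.10
    fraction_shared: float = 0.25
    fraction_null: float = 0.50
    n_latent_factors: int = 5
    gwas_n: int = 10_000
    seed: int = 0

    # cohort structure
    related_pair_fraction: float = 0.10    # fraction of donors in first-degree pairs
    variant_spacing: int = 1_000           # bp between adjacent variants
    h2_polygenic: float = 0.30
    covariate_effect_sd: float = 0.20
    latent_effect_sd: float = 0.40
    celltype_effect_scale: float = 2.5     # offsets attenuation by fractions < 1
    associated_main_share: float = 0.5     # main-effect share of an 'associated' effect

    # locus sharing
    n_multigenic_groups: int = 8
    multigenic_group_size: tuple[int, int] = (2, 3)
    n_antisense_pairs: int = 10
    antisense_shared_fraction: float = 0.6

    # isoforms
    usage_qtl_fraction: float = 0.30
    usage_independent_fraction: float = 0.5  # usage-eQTL distinct from the gene's
    usage_effect: float = 1.0
    usage_noise_sd: float = 0.30

    # expression scale
    tpm_log_mean: float = np.log(30.0)
    tpm_log_sd: float = 1.0
    tpm_scale: float = 0.5
    low_expression_fraction: float = 0.05  # null genes pushed below the TPM filter

    # GWAS
    gwas_traits: tuple[str, ...] = ("cardiac_trait",)
    gwas_h4_fraction: float = 0.15         # of non-null genes
    gwas_h3_fraction: float = 0.10
    gwas_effect: float = 0.10              # standardized units in the GWAS cohort
    gwas_null_loci: int = 10
    h3_max_r2: float = 0.2

    def __post_init__(self) -> None:
        fractions = (
            self.fraction_specific
            + self.fraction_associated
            + self.fraction_shared
            + self.fraction_null
        )
        if abs(fractions - 1.0) > 1e-12:
            raise ValueError(f"label fractions sum to {fractions}, not 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} must lie in (0, 0.5]")
        if self.n_variants_per_locus < 2:
            raise ValueError("n_variants_per_locus must be at least 2")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.n_individuals > self.n_samples:
            raise ValueError("n_individuals cannot exceed n_samples")
        if self.gwas_n < 1000:
            raise ValueError("gwas_n must be at least 1000")

    @property
    def binary_contexts(self) -> list[tuple[str, str]]:
        return [
            (name, kind)
            for kind in ("stage", "organ", "tissue")
            for name in self.contexts.get(kind, [])
        ]

    @property
    def cell_types(self) -> list[str]:
        return list(self.contexts.get("cell_type", []))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tpm_log_mean"] = float(self.tpm_log_mean)
        return d
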