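"""Shared study configuration and paths for the analysis drivers.

Every driver regenerates the same synthetic cohort deterministically from
STUDY_CONFIG (cheap, seconds) and reads/writes tables under results/.
"""

from __future__ import annotations

import time
import warnings
from pathlib import Path

import numpy as np

from cardioqtl import preprocess as pp
from cardioqtl.simdata import SimulationConfig, simulate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY_CONFIG = SimulationConfig(
    n_samples=400,
    n_individuals=330,
    n_genes=120,
    n_variants_per_locus=200,
    n_multigenic_groups=6,
    n_antisense_pairs=8,
    related_pair_fraction=0.12,
    gwas_n=10_000,
    seed=42,
)


def get_study():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(STUDY_CONFIG)


def get_pipeline_state(study, n_pcs: int = 5, n_latent: int = 5):
    """Recompute the preprocessed state (filters, normalization, kinship,
    PCs, latent factors) — deterministic given the study."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr = pp.filter_expressed_genes(study.expr_genes)
        norm = pp.inverse_normal_transform(expr)
        iso = pp.filter_isoforms(study.expr_isoforms)
        iso_norm = pp.inverse_normal_transform(
            type(iso)(features=iso.features, samples=iso.samples,
                      values=iso.usage, state="tpm")
        )
        panel = pp.filter_variants(study.panel, expr)
        kinship = pp.compute_kinship(panel)
        pcs = pp.compute_genotype_pcs(panel, k=n_pcs)
        latent = pp.expression_latent_factors(norm.values, n_latent)
        covariates = np.column_stack([study.covariate_matrix, pcs, latent])
    return {
        "expr": expr, "norm": norm, "iso": iso, "iso_norm": iso_norm,
        "panel": panel, "kinship": kinship, "covariates": covariates,
    }


class step_timer:
    def __init__(self, label: str):
        self.label = label

    def __enter__(self):
        self.t0 = time.time()
        print(f"[{self.label}] ...", flush=True)
        return self

    def __exit__(self, *exc):
        print(f"[{self.label}] done in {time.time() - self.t0:.1f}s", flush=True)
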