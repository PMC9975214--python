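"""Sample-, context- and covariate-level structure of the synthetic cohort,
and the top-level ``simulate_cohort`` orchestrator."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..types import ContextDefinition, GenotypePanel, GWASSummaryStats, TISSUE_TO_ORGAN
from .config import (
    ADULT_TISSUE_WEIGHTS,
    STAGE_DONOR_FRACTION,
    STAGE_SAMPLE_FRACTION,
    SimulationConfig,
)
from .expression import simulate_expression
from .genotypes import related_pairs, simulate_genotypes, true_relationship
from .gwas_sim import simulate_gwas_summary
from .truth import build_truth

# cell-type Dirichlet concentrations per tissue group (8 cell types in the
# order of DEFAULT_CONTEXT_NAMES['cell_type']); heart tissues are cardiac-
# muscle rich, arteria smooth-muscle rich, iPSC-CVPC cardiac-muscle rich
# with a fetal-like endocardial share.
_ALPHA = {
    "ipsc": np.array([10.0, 1.0, 1.5, 1.5, 0.8, 0.5, 2.5, 0.7]),
    "heart": np.array([9.0, 1.5, 2.0, 2.5, 1.5, 0.8, 1.0, 1.0]),
    "arteria": np.array([1.0, 9.0, 2.5, 2.5, 1.5, 0.5, 0.5, 1.5]),
}


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    panel: GenotypePanel
    locus_slices: list[slice]
    truth: pd.DataFrame
    samples: pd.DataFrame              # sample_id, individual, stage, tissue, organ
    covariates: pd.DataFrame           # sex, read_count, pct_autosomal, pct_mito
    cell_fractions: pd.DataFrame       # per sample x 8 cell types
    contexts: list[ContextDefinition]
    expr_genes: "ExpressionMatrix"
    expr_isoforms: "ExpressionMatrix"
    latent_genes: np.ndarray           # model-scale expression (oracle use)
    relationship: np.ndarray           # true sample-level additive relationship
    gwas: dict[str, GWASSummaryStats]

    @property
    def covariate_matrix(self) -> np.ndarray:
        return self.covariates[
            ["sex", "read_count", "pct_autosomal", "pct_mito"]
        ].to_numpy(dtype=float)


def assign_samples(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Map samples to donors, stages and tissues in the study proportions.

    iPSC-CVPC donors may contribute several fetal-like samples; adult donors
    may contribute several distinct tissues (repeated-donor structure).
    """
    n = config.n_samples
    n_ind = config.n_individuals
    n_ipsc = int(round(STAGE_SAMPLE_FRACTION * n))
    n_adult = n - n_ipsc
    n_ipsc_donors = max(1, int(round(STAGE_DONOR_FRACTION * n_ind)))
    ipsc_donors = np.arange(n_ipsc_donors)
    adult_donors = np.arange(n_ipsc_donors, n_ind)

    tissues = list(ADULT_TISSUE_WEIGHTS)
    weights = np.array([ADULT_TISSUE_WEIGHTS[t] for t in tissues])
    counts = np.floor(weights * n_adult).astype(int)
    while counts.sum() < n_adult:
        counts[int(np.argmax(weights * n_adult - counts))] += 1

    rows = []
    # every donor appears at least once where headroom allows
    ipsc_assign = list(ipsc_donors[: min(n_ipsc, len(ipsc_donors))])
    while len(ipsc_assign) < n_ipsc:
        ipsc_assign.append(int(rng.choice(ipsc_donors)))
    for ind in ipsc_assign:
        rows.append({"individual": int(ind), "stage": "iPSC-CVPC", "tissue": "", "organ": ""})

    adult_assign = list(adult_donors[: min(n_adult, len(adult_donors))])
    while len(adult_assign) < n_adult:
        adult_assign.append(int(rng.choice(adult_donors)))
    tissue_labels = np.repeat(tissues, counts)
    tissue_labels = tissue_labels[rng.permutation(len(tissue_labels))]
    for ind, t in zip(adult_assign, tissue_labels):
        rows.append(
            {"individual": int(ind), "stage": "adult", "tissue": t, "organ": TISSUE_TO_ORGAN[t]}
        )
    df = pd.DataFrame(rows)
    df.insert(0, "sample_id", [f"S{i:04d}" for i in range(len(df))])
    return df


def simulate_cell_fractions(
    samples: pd.DataFrame, cell_types: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    fracs = np.empty((len(samples), len(cell_types)))
    for i, row in samples.iterrows():
        if row["stage"] == "iPSC-CVPC":
            alpha = _ALPHA["ipsc"]
        elif row["organ"] == "heart":
            alpha = _ALPHA["heart"]
        else:
            alpha = _ALPHA["arteria"]
        fracs[i] = rng.dirichlet(alpha[: len(cell_types)])
    return pd.DataFrame(fracs, columns=cell_types, index=samples["sample_id"]).reset_index()


def build_contexts(
    config: SimulationConfig, samples: pd.DataFrame, cell_fractions: pd.DataFrame
) -> list[ContextDefinition]:
    out = []
    stage = samples["stage"].to_numpy()
    for name in config.contexts.get("stage", []):
        out.append(ContextDefinition(name, "stage", (stage == name).astype(float)))
    organ = samples["organ"].to_numpy()
    for name in config.contexts.get("organ", []):
        out.append(ContextDefinition(name, "organ", (organ == name).astype(float)))
    tissue = samples["tissue"].to_numpy()
    for name in config.contexts.get("tissue", []):
        out.append(ContextDefinition(name, "tissue", (tissue == name).astype(float)))
    for name in config.cell_types:
        out.append(
            ContextDefinition(name, "cell_type", cell_fractions[name].to_numpy(dtype=float))
        )
    return out


def simulate_covariates(samples: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    n_ind = samples["individual"].max() + 1
    sex_by_ind = rng.integers(0, 2, size=n_ind)
    return pd.DataFrame(
        {
            "sample_id": samples["sample_id"],
            "sex": sex_by_ind[samples["individual"]],
            "read_count": rng.standard_normal(len(samples)),
            "pct_autosomal": rng.standard_normal(len(samples)),
            "pct_mito": rng.standard_normal(len(samples)),
        }
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedStudy:
    """Generate the complete synthetic study from one seed.

    All randomness flows from one seed sequence with deterministically
    spawned sub-streams, so identical configs produce identical studies.
    """
    ss = np.random.SeedSequence(config.seed)
    (s_struct, s_geno, s_truth, s_expr, s_gwas) = [
        np.random.default_rng(c) for c in ss.spawn(5)
    ]

    samples = assign_samples(config, s_struct)
    pairs = related_pairs(config.n_individuals, config.related_pair_fraction, s_struct)
    sample_to_individual = samples["individual"].to_numpy()
    panel, locus_slices = simulate_genotypes(
        config, rng=s_geno, pairs=pairs, sample_to_individual=sample_to_individual
    )
    panel.samples = samples["sample_id"].tolist()
    relationship = true_relationship(config.n_individuals, pairs, sample_to_individual)

    truth = build_truth(config, panel, locus_slices, s_truth)
    cell_fractions = simulate_cell_fractions(samples, config.cell_types, s_struct)
    contexts = build_contexts(config, samples, cell_fractions)
    covariates = simulate_covariates(samples, s_struct)

    expr_genes, expr_isoforms, latent = simulate_expression(
        config, panel, truth, contexts, covariates, relationship, s_expr
    )
    gwas = simulate_gwas_summary(config, panel, truth, locus_slices, s_gwas)

    return SimulatedStudy(
        config=config,
        panel=panel,
        locus_slices=locus_slices,
        truth=truth,
        samples=samples,
        covariates=covariates,
        cell_fractions=cell_fractions,
        contexts=contexts,
        expr_genes=expr_genes,
        expr_isoforms=expr_isoforms,
        latent_genes=latent,
        relationship=relationship,
        gwas=gwas,
    )
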