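"""Generative model for gene- and isoform-level expression.

Model-scale expression for gene g in sample i:

    y_gi = sum_p gamma_gp C_ip + sum_f lambda_gf F_if + a_gi
           + b X_i + b3 X_i Z_i + e_gi

with C technical covariates, F latent confounding factors, a a polygenic
term with covariance h2 * A (A the pedigree relationship), X the causal
variant's standardized dosage, Z the planted context (indicator or cell
fraction), and e Gaussian noise scaled so the non-genetic variance from
the polygenic + noise components is 1 (effects are in those SD units).
Label semantics: 'shared' plants b only; 'specific' plants b3 only (no
main effect); 'associated' plants both with the same sign so the
in-context slope b + b3 exceeds the out-of-context slope b.

TPM values are a monotone exponential map of y; isoform usage follows a
logistic-normal simplex model with planted usage-eQTLs acting in opposite
directions on two isoforms, so usage effects cancel at the gene level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..types import ContextDefinition, ExpressionMatrix, GenotypePanel
from .config import SimulationConfig


def _standardized_dosage(panel: GenotypePanel, variant_id: str) -> np.ndarray:
    j = panel.variants.index[panel.variants["id"] == variant_id][0]
    x = panel.dosages[:, j].astype(float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_expression(
    config: SimulationConfig,
    panel: GenotypePanel,
    truth: pd.DataFrame,
    contexts: list[ContextDefinition],
    covariates: pd.DataFrame,
    relationship: np.ndarray,
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, ExpressionMatrix, np.ndarray]:
    """Returns (gene TPM matrix, isoform TPM+usage matrix, model-scale gene
    expression). The model-scale matrix is the oracle surface for tests that
    check the linear model directly."""
    n = panel.n_samples
    ctx_by_name = {c.name: c for c in contexts}
    cmat = covariates[["sex", "read_count", "pct_autosomal", "pct_mito"]].to_numpy(dtype=float)
    factors = rng.standard_normal((n, config.n_latent_factors))

    # one Cholesky of the pedigree relationship serves every gene
    h2 = config.h2_polygenic
    chol = np.linalg.cholesky(relationship + 1e-8 * np.eye(n))

    n_genes = len(truth)
    latent = np.empty((n_genes, n))
    gene_rngs = [np.random.default_rng(c) for c in
                 np.random.SeedSequence(rng.integers(2**31)).spawn(n_genes)]

    for i, row in truth.iterrows():
        g = gene_rngs[i]
        gamma = g.normal(0.0, config.covariate_effect_sd, size=cmat.shape[1])
        lam = g.normal(0.0, config.latent_effect_sd, size=config.n_latent_factors)
        y = cmat @ gamma + factors @ lam
        y += np.sqrt(h2) * (chol @ g.standard_normal(n))
        y += np.sqrt(1.0 - h2) * g.standard_normal(n)
        if row["label"] != "null" and row["causal_variant"]:
            x = _standardized_dosage(panel, row["causal_variant"])
            b = row["effect"]
            if row["label"] == "shared":
                y += b * x
            else:
                z = ctx_by_name[row["context"]].values
                b3 = b
                if row["context_kind"] == "cell_type":
                    b3 = b * config.celltype_effect_scale
                if row["label"] == "specific":
                    y += b3 * x * z
                else:  # associated: main effect plus same-sign interaction
                    y += config.associated_main_share * b * x + (
                        (1 - config.associated_main_share) * b3
                    ) * x * z
        latent[i] = y

    # monotone map to a positive TPM-like scale
    mu = truth["low_expression"].map(
        {True: np.log(0.1), False: config.tpm_log_mean}
    ).to_numpy() + np.array([g.normal(0, config.tpm_log_sd) for g in gene_rngs])
    tpm = np.exp(mu[:, None] + config.tpm_scale * latent)

    gene_features = pd.DataFrame(
        {
            "id": truth["gene_id"],
            "gene_id": truth["gene_id"],
            "chrom": truth["chrom"],
            "start": truth["start"],
            "end": truth["end"],
            "strand": truth["strand"],
            "level": "gene",
        }
    )
    expr_genes = ExpressionMatrix(
        features=gene_features, samples=list(panel.samples), values=tpm, state="tpm"
    )

    # isoforms: logistic-normal usage within each gene
    iso_rows, iso_tpm, iso_usage = [], [], []
    for i, row in truth.iterrows():
        g = gene_rngs[i]
        k = int(row["n_isoforms"])
        base = np.log(g.dirichlet(np.full(k, 5.0)) + 1e-6)
        eta = base[None, :] + g.normal(0.0, config.usage_noise_sd, size=(n, k))
        if row["usage_qtl_variant"]:
            xu = _standardized_dosage(panel, row["usage_qtl_variant"])
            eta[:, 0] += row["usage_effect"] * xu
            eta[:, 1] -= row["usage_effect"] * xu
        usage = np.exp(eta)
        usage /= usage.sum(axis=1, keepdims=True)
        for t in range(k):
            iso_rows.append(
                {
                    "id": f"{row['gene_id']}.{t + 1}",
                    "gene_id": row["gene_id"],
                    "chrom": row["chrom"],
                    "start": row["start"],
                    "end": row["end"],
                    "strand": row["strand"],
                    "level": "isoform",
                }
            )
            iso_tpm.append(tpm[i] * usage[:, t])
            iso_usage.append(usage[:, t])
    expr_isoforms = ExpressionMatrix(
        features=pd.DataFrame(iso_rows),
        samples=list(panel.samples),
        values=np.vstack(iso_tpm),
        state="tpm",
        usage=np.vstack(iso_usage),
    )
    return expr_genes, expr_isoforms, latent
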