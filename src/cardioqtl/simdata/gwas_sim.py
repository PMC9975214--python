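"""Simulated GWAS summary statistics from an independent large cohort
sharing the panel's LD law.

For every locus carrying a planted GWAS relation (H4: causal variant equal
to the eQTL causal variant; H3: a distinct variant in low LD with it) a
fresh cohort of ``gwas_n`` unrelated individuals is drawn from the same
haplotype model, a quantitative trait is generated from the planted causal
variant, and per-variant marginal OLS effect estimates, standard errors,
p-values and allele frequencies are reported — exactly the columns a GWAS
summary file provides. A configurable number of null loci (no causal
variant) completes the genome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ..ld import ld_from_haplotypes
from ..types import GenotypePanel, GWASSummaryStats
from .config import SimulationConfig
from .genotypes import simulate_haplotypes


def _marginal_ols(genotypes: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-variant simple regression of y on each genotype column."""
    n = len(y)
    g = genotypes - genotypes.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", g, g)
    sxy = yc @ g
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = float(yc @ yc) - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    bad = sxx <= 0
    beta[bad], se[bad], p[bad] = np.nan, np.nan, np.nan
    return beta, se, p


def simulate_locus_gwas(
    config: SimulationConfig,
    panel: GenotypePanel,
    locus_slice: slice,
    causal_variant: str | None,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Summary statistics for one locus from a fresh cohort of gwas_n."""
    sub = panel.variants.iloc[locus_slice]
    freqs = panel.haplotypes[:, locus_slice].mean(axis=0)
    freqs = np.clip(freqs, 1e-4, 1 - 1e-4)
    haps = simulate_haplotypes(2 * config.gwas_n, freqs, config.ld_rho, rng)
    counts = (haps[0::2] + haps[1::2]).astype(float)
    y = rng.standard_normal(config.gwas_n)
    if causal_variant is not None:
        j_abs = panel.variants.index[panel.variants["id"] == causal_variant][0]
        j = int(j_abs) - locus_slice.start
        x = counts[:, j]
        sd = x.std()
        if sd > 0:
            y = y + config.gwas_effect * (x - x.mean()) / sd
    beta, se, p = _marginal_ols(counts, y)
    return pd.DataFrame(
        {
            "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "ref": sub["ref"].to_numpy(),
            "alt": sub["alt"].to_numpy(),
            "id": sub["id"].to_numpy(),
            "beta": beta,
            "se": se,
            "pval": p,
            "af": counts.mean(axis=0) / 2.0,
        }
    )


def simulate_gwas_summary(
    config: SimulationConfig,
    panel: GenotypePanel,
    truth: pd.DataFrame,
    locus_slices: list[slice],
    rng: np.random.Generator,
) -> dict[str, GWASSummaryStats]:
    """Per trait: concatenated locus summary statistics.

    H3 loci are validated once more here: if no variant in the locus has
    r^2 < the configured bound with the eQTL causal variant, locus
    construction fails loudly rather than silently planting a confounded
    'distinct' signal.
    """
    out: dict[str, list[pd.DataFrame]] = {t: [] for t in config.gwas_traits}
    id_to_idx = {v: i for i, v in enumerate(panel.variants["id"])}
    for _, row in truth.iterrows():
        if row["gwas_relation"] == "none":
            continue
        lslice = locus_slices[row["locus"]]
        if row["gwas_relation"] == "H3":
            e_idx = id_to_idx[row["causal_variant"]]
            g_idx = id_to_idx[row["gwas_causal_variant"]]
            r2, _ = ld_from_haplotypes(
                panel.haplotypes[:, e_idx], panel.haplotypes[:, g_idx]
            )
            if not (np.isfinite(r2) and r2 < config.h3_max_r2):
                raise RuntimeError(
                    f"H3 locus for {row['gene_id']}: no variant with r2 < "
                    f"{config.h3_max_r2} available"
                )
        out[row["gwas_trait"]].append(
            simulate_locus_gwas(
                config, panel, lslice, row["gwas_causal_variant"], rng
            )
        )
    # null loci: no causal variant, spread over loci without a GWAS relation
    unused = [
        i for i in range(len(locus_slices))
        if not ((truth["locus"] == i) & (truth["gwas_relation"] != "none")).any()
    ]
    for k, locus in enumerate(unused[: config.gwas_null_loci]):
        trait = config.gwas_traits[k % len(config.gwas_traits)]
        out[trait].append(
            simulate_locus_gwas(config, panel, locus_slices[locus], None, rng)
        )
    result = {}
    for trait, blocks in out.items():
        table = (
            pd.concat(blocks, ignore_index=True)
            if blocks
            else pd.DataFrame(
                columns=["chrom", "pos", "ref", "alt", "id", "beta", "se", "pval", "af"]
            )
        )
        result[trait] = GWASSummaryStats(trait=trait, table=table, n=config.gwas_n)
    return result
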