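"""Haplotype and genotype simulation with tunable LD and explicit
first-degree-relative blocks.

Haplotypes come from a Gaussian-copula first-order chain: a latent AR(1)
process with autocorrelation ``ld_rho`` is thresholded at the normal
quantile of each variant's allele frequency, so marginal frequencies are
exact and LD decays geometrically with distance. Related pairs share one
transmitted haplotype at every locus (kinship coefficient exactly 0.25 in
expectation), which keeps pedigree assertions sharp. Diploid dosages are
encoded {0, 0.5, 1}.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ..types import GenotypePanel
from .config import SimulationConfig

REF_ALT = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


def simulate_haplotypes(
    n_haplotypes: int, freqs: np.ndarray, ld_rho: float, rng: np.random.Generator
) -> np.ndarray:
    """(n_haplotypes, m) 0/1 matrix from the latent-AR(1) copula."""
    m = len(freqs)
    z = np.empty((n_haplotypes, m))
    z[:, 0] = rng.standard_normal(n_haplotypes)
    if m > 1:
        noise = rng.standard_normal((n_haplotypes, m - 1))
        c = np.sqrt(1.0 - ld_rho**2)
        for j in range(1, m):
            z[:, j] = ld_rho * z[:, j - 1] + c * noise[:, j - 1]
    thresholds = stats.norm.ppf(freqs)
    return (z < thresholds[None, :]).astype(np.int8)


def related_pairs(n_individuals: int, related_pair_fraction: float,
                  rng: np.random.Generator) -> list[tuple[int, int]]:
    """Disjoint first-degree pairs covering ~``related_pair_fraction`` of donors."""
    n_pairs = int(np.floor(related_pair_fraction * n_individuals / 2))
    perm = rng.permutation(n_individuals)
    return [(int(perm[2 * k]), int(perm[2 * k + 1])) for k in range(n_pairs)]


def share_haplotype(haps: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    """Copy the first haplotype of each pair's first member into the second
    member, making them first-degree relatives at this locus."""
    for a, b in pairs:
        haps[2 * b] = haps[2 * a]
    return haps


def locus_positions(locus: int, m: int, spacing: int) -> tuple[str, np.ndarray]:
    """Loci cycle over 22 autosomes; successive loci on one chromosome are
    separated by a 250 kb gap, so neighbouring genes fall inside each
    other's 500 kb windows (background pairs for sharing analyses) while
    their haplotypes stay independent."""
    chrom = f"chr{(locus % 22) + 1}"
    base = 1_000_000 + (locus // 22) * (m * spacing + 250_000)
    return chrom, base + spacing * np.arange(m)


def simulate_genotypes(
    config: SimulationConfig,
    n_loci: int | None = None,
    rng: np.random.Generator | None = None,
    pairs: list[tuple[int, int]] | None = None,
    sample_to_individual: np.ndarray | None = None,
) -> tuple[GenotypePanel, list[slice]]:
    """Simulate the full multi-locus panel.

    Returns the panel (with phased haplotypes attached) and per-locus
    variant slices. When ``sample_to_individual`` is omitted, samples map
    1:1 to the first ``n_samples`` individuals.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_loci = n_loci if n_loci is not None else config.n_genes
    n_ind = config.n_individuals
    if pairs is None:
        pairs = related_pairs(n_ind, config.related_pair_fraction, rng)
    if sample_to_individual is None:
        sample_to_individual = np.arange(config.n_samples) % n_ind
    m = config.n_variants_per_locus

    hap_blocks, dose_blocks, meta = [], [], []
    slices = []
    offset = 0
    for locus in range(n_loci):
        freqs = rng.uniform(*config.maf_range, size=m)
        haps = simulate_haplotypes(2 * n_ind, freqs, config.ld_rho, rng)
        haps = share_haplotype(haps, pairs)
        counts = haps[0::2] + haps[1::2]                 # per individual, 0..2
        dosages = counts[sample_to_individual] / 2.0     # {0, 0.5, 1} per sample
        chrom, pos = locus_positions(locus, m, config.variant_spacing)
        for j in range(m):
            ref, alt = REF_ALT[j % len(REF_ALT)]
            meta.append(
                {
                    "id": f"{chrom}_{pos[j]}_{ref}_{alt}",
                    "chrom": chrom,
                    "pos": int(pos[j]),
                    "ref": ref,
                    "alt": alt,
                    "locus": locus,
                }
            )
        hap_blocks.append(haps)
        dose_blocks.append(dosages.astype(np.float64))
        slices.append(slice(offset, offset + m))
        offset += m

    variants = pd.DataFrame(meta)
    panel = GenotypePanel(
        variants=variants,
        dosages=np.concatenate(dose_blocks, axis=1),
        samples=[f"S{i:04d}" for i in range(len(sample_to_individual))],
        haplotypes=np.concatenate(hap_blocks, axis=1),
        sample_to_individual=np.asarray(sample_to_individual),
    )
    return panel, slices


def true_relationship(
    n_individuals: int,
    pairs: list[tuple[int, int]],
    sample_to_individual: np.ndarray,
) -> np.ndarray:
    """Sample-level additive relationship matrix implied by the pedigree
    (1 on the diagonal and between repeated-donor samples, 0.5 for
    first-degree pairs)."""
    a = np.eye(n_individuals)
    for i, j in pairs:
        a[i, j] = a[j, i] = 0.5
    return a[np.ix_(sample_to_individual, sample_to_individual)]
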