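"""Linkage-disequilibrium measures (r-squared and D').

Both measures derive from two-locus haplotype frequencies. When phased
haplotypes are available they are counted directly; otherwise frequencies
are estimated from unphased diploid genotypes with the classic two-locus
EM algorithm (only the double-heterozygote class is phase-ambiguous).
"""

from __future__ import annotations

import numpy as np


def _ld_from_hap_freqs(p_ab: float, p_a: float, p_b: float) -> tuple[float, float]:
    """(r2, D') from the AB haplotype frequency and the two allele frequencies."""
    d = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        return np.nan, np.nan
    r2 = d * d / denom
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = np.nan if d_max == 0 else abs(d) / d_max
    return float(r2), float(dprime)


def ld_from_haplotypes(h1: np.ndarray, h2: np.ndarray) -> tuple[float, float]:
    """r2 and D' counted from phased 0/1 haplotype vectors."""
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    p_a = h1.mean()
    p_b = h2.mean()
    p_ab = float(np.mean(h1 * h2))
    return _ld_from_hap_freqs(p_ab, p_a, p_b)


def em_haplotype_freq(
    g1: np.ndarray,
    g2: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> tuple[float, float, float]:
    """EM estimate of (p_AB, p_A, p_B) from unphased allele counts in {0,1,2}.

    Missing genotypes (NaN) at either locus drop the sample pair.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    keep = ~(np.isnan(g1) | np.isnan(g2))
    g1, g2 = g1[keep], g2[keep]
    n = len(g1)
    if n == 0:
        return np.nan, np.nan, np.nan
    p_a = g1.mean() / 2.0
    p_b = g2.mean() / 2.0
    # 3x3 genotype-pair counts
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((g1 == i) & (g2 == j))
    n_dh = counts[1, 1]  # double heterozygotes: phase unknown
    # known haplotype counts contributed by the eight unambiguous classes
    base_ab = (
        2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    )
    p_ab = p_a * p_b if p_a * p_b > 0 else 0.25
    total_haps = 2.0 * n
    for _ in range(max_iter):
        p_aB = p_a - p_ab
        p_Ab = p_b - p_ab
        p_00 = 1 - p_a - p_b + p_ab  # haplotype carrying neither alt allele
        num = p_ab * p_00
        den = num + max(p_aB, 0) * max(p_Ab, 0)
        frac = 0.5 if den <= 0 else num / den
        new_ab = (base_ab + n_dh * frac) / total_haps
        if abs(new_ab - p_ab) < tol:
            p_ab = new_ab
            break
        p_ab = new_ab
    return float(p_ab), float(p_a), float(p_b)


def ld_from_genotypes(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float]:
    """r2 and D' from unphased allele-count vectors via the EM estimate."""
    p_ab, p_a, p_b = em_haplotype_freq(g1, g2)
    if np.isnan(p_ab):
        return np.nan, np.nan
    return _ld_from_hap_freqs(p_ab, p_a, p_b)


class LDPanel:
    """LD lookups over a genotype panel keyed by variant id.

    Uses phased haplotypes when the panel carries them, otherwise the EM
    estimate on dosages (converted to allele counts).
    """

    def __init__(self, panel) -> None:
        self._panel = panel
        self._index = {v: i for i, v in enumerate(panel.variants["id"])}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def _pair(self, id1: str, id2: str) -> tuple[float, float]:
        i, j = self._index[id1], self._index[id2]
        if self._panel.haplotypes is not None:
            return ld_from_haplotypes(
                self._panel.haplotypes[:, i], self._panel.haplotypes[:, j]
            )
        return ld_from_genotypes(
            2.0 * self._panel.dosages[:, i], 2.0 * self._panel.dosages[:, j]
        )

    def r2(self, id1: str, id2: str) -> float:
        if id1 == id2:
            return 1.0
        return self._pair(id1, id2)[0]

    def d_prime(self, id1: str, id2: str) -> float:
        if id1 == id2:
            return 1.0
        return self._pair(id1, id2)[1]
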