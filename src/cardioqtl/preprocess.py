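"""Expression and variant filters, rank-based normalization, kinship,
genotype PCs, and the latent-factor-count selection sweep.

Filter thresholds follow the study design: genes expressed at TPM >= 1 in
at least 10% of samples; isoforms at TPM >= 1 and usage > 10% in at least
10% of samples with at least two qualifying isoforms per gene; variants at
MAF > 1% (per cohort stratum when declared), Hardy-Weinberg p > 1e-6,
call rate >= 99%, and within 500 kb of an expressed gene.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, GenotypePanel

CIS_WINDOW = 500_000


# --------------------------------------------------------------- expression


def filter_expressed_genes(
    expr: ExpressionMatrix, tpm_min: float = 1.0, fraction: float = 0.10
) -> ExpressionMatrix:
    """Keep genes with TPM >= tpm_min in at least `fraction` of samples."""
    if expr.state != "tpm":
        raise ValueError("gene filter expects TPM-state expression")
    n = len(expr.samples)
    keep = (expr.values >= tpm_min).sum(axis=1) >= fraction * n
    if not keep.any():
        warnings.warn("no genes pass the expression filter")
    return expr.subset_features(keep)


def filter_isoforms(
    expr_iso: ExpressionMatrix,
    tpm_min: float = 1.0,
    usage_min: float = 0.10,
    fraction: float = 0.10,
    usage_strict: bool = True,
) -> ExpressionMatrix:
    """Keep isoforms qualifying (TPM >= tpm_min AND usage > usage_min) in at
    least `fraction` of samples, then drop genes with fewer than two
    qualifying isoforms. ``usage_strict=False`` switches the usage rule
    to >=."""
    if expr_iso.usage is None:
        raise ValueError("isoform filter needs both TPM and usage values")
    n = len(expr_iso.samples)
    if usage_strict:
        ok = (expr_iso.values >= tpm_min) & (expr_iso.usage > usage_min)
    else:
        ok = (expr_iso.values >= tpm_min) & (expr_iso.usage >= usage_min)
    qualifying = ok.sum(axis=1) >= fraction * n
    genes = expr_iso.features["gene_id"].to_numpy()
    counts = pd.Series(genes[qualifying]).value_counts()
    genes_ok = set(counts.index[counts >= 2])
    keep = qualifying & np.isin(genes, list(genes_ok))
    return expr_iso.subset_features(keep)


def inverse_normal_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-feature rank-based mapping to the standard normal.

    Ranks (ties averaged) map through (rank - 0.5) / n to normal quantiles;
    the result is then standardized exactly so each feature has mean 0 and
    sd 1. Cross-sample quantile normalization to a common reference followed
    by rank-to-normal reduces to this, since only the ranks survive the
    final mapping. Constant features become all-zero with a warning.
    """
    x = np.asarray(expr.values, dtype=float)
    n = x.shape[1]
    out = np.zeros_like(x)
    for i in range(x.shape[0]):
        row = x[i]
        if np.all(row == row[0]):
            warnings.warn(f"constant feature {expr.features['id'].iloc[i]}: set to zeros")
            continue
        ranks = stats.rankdata(row, method="average")
        z = stats.norm.ppf((ranks - 0.5) / n)
        z -= z.mean()
        sd = z.std()
        out[i] = z / sd if sd > 0 else z
    return ExpressionMatrix(
        features=expr.features.copy(),
        samples=list(expr.samples),
        values=out,
        state="inverse_normal",
    )


# ----------------------------------------------------------------- variants


def hwe_chi2_p(dosages: np.ndarray) -> float:
    """1-df chi-square Hardy-Weinberg test from {0, 0.5, 1} dosages."""
    d = dosages[~np.isnan(dosages)]
    n = len(d)
    if n == 0:
        return np.nan
    n0 = np.sum(d == 0.0)
    n1 = np.sum(d == 0.5)
    n2 = np.sum(d == 1.0)
    p = (2 * n2 + n1) / (2.0 * n)
    if p <= 0 or p >= 1:
        return 1.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum((obs - exp) ** 2 / exp)
    return float(stats.chi2.sf(chi2, df=1))


def variant_stats(panel: GenotypePanel) -> pd.DataFrame:
    """Recompute maf / hwe_p / call_rate from the dosage matrix."""
    d = panel.dosages
    call_rate = 1.0 - np.isnan(d).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        af = np.nanmean(d, axis=0)
    maf = np.minimum(af, 1 - af)
    hwe = np.array([hwe_chi2_p(d[:, j]) for j in range(d.shape[1])])
    stats_df = panel.variants[["id", "chrom", "pos", "ref", "alt"]].copy()
    stats_df["maf"] = maf
    stats_df["hwe_p"] = hwe
    stats_df["call_rate"] = call_rate
    return stats_df


def filter_variants(
    panel: GenotypePanel,
    expressed: ExpressionMatrix | None = None,
    maf_min: float = 0.01,
    hwe_min: float = 1e-6,
    call_rate_min: float = 0.99,
    window: int = CIS_WINDOW,
    strata: np.ndarray | None = None,
) -> GenotypePanel:
    """Apply MAF / HWE / call-rate filters and (optionally) the requirement
    of lying within `window` bp of an expressed gene (inclusive boundary).

    When ``strata`` (a per-sample cohort label array) is given, the MAF rule
    must hold within every stratum, mirroring 'MAF > 1% in both studies'.
    """
    st = variant_stats(panel)
    keep = (
        (st["maf"].to_numpy() > maf_min)
        & (st["hwe_p"].to_numpy() > hwe_min)
        & (st["call_rate"].to_numpy() >= call_rate_min)
    )
    n_all_missing = int((st["call_rate"].to_numpy() == 0).sum())
    if n_all_missing:
        warnings.warn(f"{n_all_missing} variant(s) with all-missing genotypes removed")
    if strata is not None:
        strata = np.asarray(strata)
        for s in np.unique(strata):
            sub = panel.dosages[strata == s]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                af = np.nanmean(sub, axis=0)
            maf_s = np.minimum(af, 1 - af)
            keep &= np.nan_to_num(maf_s, nan=0.0) > maf_min
    if expressed is not None:
        near = np.zeros(panel.n_variants, dtype=bool)
        pos = panel.variants["pos"].to_numpy()
        chrom = panel.variants["chrom"].to_numpy()
        for c, grp in expressed.features.groupby("chrom"):
            on_c = chrom == c
            if not on_c.any():
                continue
            starts = grp["start"].to_numpy() - window
            ends = grp["end"].to_numpy() + window
            p = pos[on_c]
            hit = np.zeros(len(p), dtype=bool)
            for s, e in zip(starts, ends):
                hit |= (p >= s) & (p <= e)
            near[on_c] = hit
        keep &= near
    out = panel.subset_variants(keep)
    out.variants = st.loc[keep].reset_index(drop=True)
    return out


# ---------------------------------------------------- kinship / genotype PCs


def _standardized_dosages(d: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages and standardize columns to unit variance
    using the binomial variance p(1-p)/2 implied by the {0,0.5,1} coding."""
    d = np.array(d, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        af = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(af, inds[1])
    var = af * (1 - af) / 2.0
    ok = var > 0
    z = np.zeros_like(d)
    z[:, ok] = (d[:, ok] - af[ok]) / np.sqrt(var[ok])
    return z


def compute_kinship(
    panel: GenotypePanel,
    af_window: tuple[float, float] = (0.30, 0.60),
    min_variants: int = 100,
) -> np.ndarray:
    """Kinship coefficients from standardized dosages of common variants.

    Restricted to variants with allele frequency inside ``af_window``; the
    standardized relationship matrix Z Z' / m is halved to the kinship-
    coefficient scale (self ~ 0.5, full sibs ~ 0.25), and eigenvalues are
    clipped at zero so the result is PSD.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        af = np.nanmean(panel.dosages, axis=0)
    inside = (af >= af_window[0]) & (af <= af_window[1])
    m = int(inside.sum())
    if m < min_variants:
        raise ValueError(
            f"only {m} variants with AF in {af_window}; need >= {min_variants} — "
            "increase the panel size or widen the AF window"
        )
    z = _standardized_dosages(panel.dosages[:, inside])
    grm = (z @ z.T) / m
    kin = 0.5 * grm
    s, u = np.linalg.eigh(0.5 * (kin + kin.T))
    if s.min() < 0:
        s = np.clip(s, 0, None)
        kin = (u * s) @ u.T
    return kin


def compute_genotype_pcs(panel: GenotypePanel, k: int = 20,
                         af_window: tuple[float, float] = (0.30, 0.60)) -> np.ndarray:
    """Top-k PCs of mean-centered, variance-standardized dosages on the same
    common-variant subset as the kinship. Sign fixed so each component's
    largest-magnitude loading is positive. k=0 returns an empty block."""
    n = panel.n_samples
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n_samples-1={n - 1}")
    if k == 0:
        return np.zeros((n, 0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        af = np.nanmean(panel.dosages, axis=0)
    inside = (af >= af_window[0]) & (af <= af_window[1])
    if not inside.any():
        inside = np.ones(panel.n_variants, dtype=bool)
    z = _standardized_dosages(panel.dosages[:, inside])
    z = z - z.mean(axis=0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = min(k, len(s))
    pcs = u[:, :k]
    for j in range(k):
        load = vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


# ------------------------------------------------- latent factors / sweep


def expression_latent_factors(values: np.ndarray, n_factors: int) -> np.ndarray:
    """Latent expression factors as the top principal components of the
    (feature x sample) matrix — the package's stand-in for an external
    latent-factor model. Returns (n_samples, n_factors)."""
    if n_factors == 0:
        return np.zeros((values.shape[1], 0))
    x = values - values.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_factors, len(s))
    f = vt[:k].T * s[:k]
    # standardize factor columns for use as covariates
    f = (f - f.mean(axis=0)) / np.where(f.std(axis=0) > 0, f.std(axis=0), 1.0)
    if k < n_factors:
        f = np.column_stack([f, np.zeros((f.shape[0], n_factors - k))])
    return f


def select_latent_factor_count(
    expr: ExpressionMatrix,
    candidates: list[int],
    panel: GenotypePanel,
    covariates: np.ndarray | None,
    kinship: np.ndarray | None = None,
    genes_per_decile: int = 20,
    q_threshold: float = 0.05,
    cis_window: int = CIS_WINDOW,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Pick the latent-factor count maximizing detected eQTLs on a
    decile-stratified gene sample.

    Expressed genes are split into ten average-TPM deciles; ``genes_per_decile``
    random genes per decile (seeded) form the evaluation set. For each
    candidate count the cis scan + gene-level correction + BH is run on those
    genes and the significant-eQTL count recorded. Ties break toward the
    smaller count. Returns (best_count, sweep table).
    """
    from .eqtl import map_feature_primaries  # local import to avoid a cycle

    if not candidates:
        raise ValueError("no candidate factor counts")
    rng = np.random.default_rng(seed)
    mean_tpm = expr.values.mean(axis=1)
    deciles = pd.qcut(mean_tpm, 10, labels=False, duplicates="drop")
    chosen: list[int] = []
    for d in np.unique(deciles):
        idx = np.flatnonzero(deciles == d)
        quota = genes_per_decile
        if len(idx) < quota:
            warnings.warn(f"decile {d}: only {len(idx)} genes; quota reduced")
            quota = len(idx)
        chosen.extend(rng.choice(idx, size=quota, replace=False).tolist())
    sub = expr.subset_features(np.array(sorted(chosen)))
    sub_norm = inverse_normal_transform(sub)

    rows = []
    for n_factors in candidates:
        factors = expression_latent_factors(
            inverse_normal_transform(expr).values, n_factors
        )
        cov = factors if covariates is None else np.column_stack([covariates, factors])
        res = map_feature_primaries(
            sub_norm, panel, cov, kinship, cis_window=cis_window
        )
        from statsmodels.stats.multitest import multipletests

        ps = res["corrected_p"].to_numpy()
        ok = ~np.isnan(ps)
        n_sig = 0
        if ok.any():
            rej, _, _, _ = multipletests(ps[ok], alpha=q_threshold, method="fdr_bh")
            n_sig = int(rej.sum())
        rows.append({"n_factors": n_factors, "n_eqtls": n_sig})
    sweep = pd.DataFrame(rows)
    best = sweep.sort_values(["n_eqtls", "n_factors"], ascending=[False, True])
    return int(best["n_factors"].iloc[0]), sweep
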