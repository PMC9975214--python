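"""Kinship-aware cis-eQTL mapping: per-feature scans, LD-aware gene-level
correction via an effective number of tests, stepwise conditional signals,
and genome-wide Benjamini-Hochberg correction.

The two-step multiple-testing scheme corrects each feature's minimum p by
the effective number of tests in its cis window (estimated from the
eigenvalues of the local genotype correlation matrix, windowed for large
loci), then applies BH across all features' corrected lead p-values with a
q < 0.05 significance rule.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .lmm import LMMEngine
from .preprocess import CIS_WINDOW
from .types import EqtlSignal, ExpressionMatrix, GenotypePanel, ScanResult

MAX_CONDITIONAL = 5
Q_SIGNIFICANT = 0.05


# ------------------------------------------------------------ gene-level MT


def effective_tests(
    genotypes: np.ndarray, window: int = 200, variance_capture: float = 0.99
) -> int:
    """Effective number of tests from the eigenvalues of the cis genotype
    correlation matrix: within each block of ``window`` variants, the
    smallest m whose top-m eigenvalues capture >= ``variance_capture`` of
    the total; blocks are summed. Zero-variance columns count as zero."""
    g = np.asarray(genotypes, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    sd = g.std(axis=0)
    g = g[:, sd > 0]
    m = g.shape[1]
    if m == 0:
        return 1
    if m == 1:
        return 1
    total = 0
    for start in range(0, m, window):
        block = g[:, start : start + window]
        if block.shape[1] == 1:
            total += 1
            continue
        corr = np.corrcoef(block, rowvar=False)
        ev = np.linalg.eigvalsh(corr)[::-1]
        ev = np.clip(ev, 0, None)
        cum = np.cumsum(ev)
        k = int(np.searchsorted(cum, variance_capture * cum[-1], side="left")) + 1
        total += min(k, block.shape[1])
    return max(total, 1)


def gene_level_correction(
    per_variant_p: np.ndarray, cis_genotypes: np.ndarray, **meff_kwargs
) -> float:
    """Corrected lead p = min(1, p_min * M_eff)."""
    p = np.asarray(per_variant_p, dtype=float)
    ok = np.isfinite(p)
    if not ok.any():
        return np.nan
    m_eff = effective_tests(cis_genotypes, **meff_kwargs)
    return float(min(1.0, np.nanmin(p[ok]) * m_eff))


def genome_wide_fdr(corrected_ps: np.ndarray, alpha: float = Q_SIGNIFICANT):
    """BH step-up q-values over one corrected p per feature.

    Returns (q, significant mask, p_cutoff) where p_cutoff is the largest
    corrected p accepted at level alpha (NaN if none) — conditional-scan
    iterations reuse it as their significance rule so conditional leads are
    judged against the same genome-wide family as primaries.
    """
    p = np.asarray(corrected_ps, dtype=float)
    q = np.full_like(p, np.nan)
    sig = np.zeros(len(p), dtype=bool)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return q, sig, np.nan
    rej, qv, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
    q[ok] = qv
    sig[ok] = rej
    cutoff = float(p[ok][rej].max()) if rej.any() else np.nan
    return q, sig, cutoff


# ----------------------------------------------------------------- cis scan


def cis_mask(
    variants: pd.DataFrame, chrom, start: int, end: int, window: int = CIS_WINDOW
) -> np.ndarray:
    pos = variants["pos"].to_numpy()
    return (
        (variants["chrom"].to_numpy() == chrom)
        & (pos >= start - window)
        & (pos <= end + window)
    )


def lmm_scan(
    y: np.ndarray,
    genotypes: np.ndarray,
    variant_ids: np.ndarray,
    covariates: np.ndarray | None,
    engine: LMMEngine,
) -> ScanResult:
    """Per-variant Wald statistics for one feature; variance components are
    estimated once under the covariates-only null and reused across variants."""
    null = engine.fit_null(y, covariates)
    beta, se, p = engine.scan(null, genotypes)
    return ScanResult(variant_ids=np.asarray(variant_ids), beta=beta, se=se, p=p)


def conditional_scan(
    y: np.ndarray,
    genotypes: np.ndarray,
    variant_ids: np.ndarray,
    covariates: np.ndarray | None,
    engine: LMMEngine,
    primary: EqtlSignal,
    p_cutoff: float,
    max_conditional: int = MAX_CONDITIONAL,
    collinearity_r2: float = 0.95,
    **meff_kwargs,
) -> list[EqtlSignal]:
    """Stepwise conditional signals: prior lead dosages enter as fixed
    covariates, the scan repeats, and iteration stops when the new lead's
    corrected p exceeds the genome-wide cutoff or ``max_conditional``
    signals are found. Candidate leads nearly collinear with prior leads
    (r^2 > ``collinearity_r2``) are skipped in favour of the next-best."""
    variant_ids = np.asarray(variant_ids)
    id_to_col = {v: j for j, v in enumerate(variant_ids)}
    leads = [primary.lead_id]
    out: list[EqtlSignal] = []
    if not np.isfinite(p_cutoff):
        return out
    for rank in range(1, max_conditional + 1):
        lead_cols = [id_to_col[v] for v in leads]
        lead_geno = genotypes[:, lead_cols]
        cov = (
            lead_geno
            if covariates is None
            else np.column_stack([covariates, lead_geno])
        )
        scan = lmm_scan(y, genotypes, variant_ids, cov, engine)
        order = np.argsort(np.where(np.isnan(scan.p), np.inf, scan.p))
        lead_idx = None
        for j in order:
            if not np.isfinite(scan.p[j]):
                break
            g_j = genotypes[:, j]
            r2s = [
                np.corrcoef(g_j, genotypes[:, c])[0, 1] ** 2
                if genotypes[:, c].std() > 0 and g_j.std() > 0
                else 1.0
                for c in lead_cols
            ]
            if max(r2s) > collinearity_r2:
                continue
            lead_idx = int(j)
            break
        if lead_idx is None:
            break
        corrected = gene_level_correction(scan.p, genotypes, **meff_kwargs)
        if not (corrected <= p_cutoff):
            break
        sig = EqtlSignal(
            feature_id=primary.feature_id,
            level=primary.level,
            signal_rank=rank,
            lead_id=str(variant_ids[lead_idx]),
            scan=scan,
            corrected_p=corrected,
            conditioned_on=tuple(leads),
        )
        out.append(sig)
        leads.append(sig.lead_id)
    return out


# --------------------------------------------------------------- pipelines


def map_feature_primaries(
    expr: ExpressionMatrix,
    panel: GenotypePanel,
    covariates: np.ndarray | None,
    kinship: np.ndarray | None,
    cis_window: int = CIS_WINDOW,
    **meff_kwargs,
) -> pd.DataFrame:
    """Primary cis scan for every feature: lead variant, lead stats, and the
    gene-level corrected p. Returns one row per feature (NaN when the
    feature has no cis variants)."""
    engine = LMMEngine(kinship, n=panel.n_samples)
    rows = []
    ids = panel.variants["id"].to_numpy()
    for i in range(expr.n_features):
        feat = expr.features.iloc[i]
        mask = cis_mask(panel.variants, feat["chrom"], feat["start"], feat["end"], cis_window)
        if not mask.any():
            rows.append(
                {"feature_id": feat["id"], "lead_id": None, "beta": np.nan,
                 "se": np.nan, "p": np.nan, "corrected_p": np.nan, "n_cis": 0}
            )
            continue
        g = panel.dosages[:, mask]
        scan = lmm_scan(expr.values[i], g, ids[mask], covariates, engine)
        j = scan.lead_index
        rows.append(
            {
                "feature_id": feat["id"],
                "lead_id": str(scan.variant_ids[j]),
                "beta": float(scan.beta[j]),
                "se": float(scan.se[j]),
                "p": float(scan.p[j]),
                "corrected_p": gene_level_correction(scan.p, g, **meff_kwargs),
                "n_cis": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def map_eqtls(
    expr: ExpressionMatrix,
    panel: GenotypePanel,
    covariates: np.ndarray | None,
    kinship: np.ndarray | None,
    level: str = "gene",
    cis_window: int = CIS_WINDOW,
    max_conditional: int = MAX_CONDITIONAL,
    alpha: float = Q_SIGNIFICANT,
    **meff_kwargs,
) -> tuple[list[EqtlSignal], pd.DataFrame]:
    """Full two-step eQTL mapping: primary scans, genome-wide BH, then
    stepwise conditional signals for significant features.

    Returns (signals, feature table with q-values). Signals carry full
    per-variant summary statistics (conditional signals use conditioned
    stats) for downstream fine-mapping and colocalization.
    """
    if expr.state != "inverse_normal":
        warnings.warn("expression is not inverse-normal transformed")
    engine = LMMEngine(kinship, n=panel.n_samples)
    ids = panel.variants["id"].to_numpy()
    primaries: list[EqtlSignal | None] = []
    feature_rows = []
    for i in range(expr.n_features):
        feat = expr.features.iloc[i]
        mask = cis_mask(panel.variants, feat["chrom"], feat["start"], feat["end"], cis_window)
        if not mask.any():
            primaries.append(None)
            feature_rows.append({"feature_id": feat["id"], "corrected_p": np.nan, "n_cis": 0})
            continue
        g = panel.dosages[:, mask]
        scan = lmm_scan(expr.values[i], g, ids[mask], covariates, engine)
        corrected = gene_level_correction(scan.p, g, **meff_kwargs)
        sig = EqtlSignal(
            feature_id=str(feat["id"]),
            level=level,
            signal_rank=0,
            lead_id=str(scan.variant_ids[scan.lead_index]),
            scan=scan,
            corrected_p=corrected,
        )
        primaries.append(sig)
        feature_rows.append(
            {"feature_id": feat["id"], "corrected_p": corrected, "n_cis": int(mask.sum())}
        )
    features = pd.DataFrame(feature_rows)
    q, sig_mask, cutoff = genome_wide_fdr(features["corrected_p"].to_numpy(), alpha=alpha)
    features["q"] = q
    features["significant"] = sig_mask

    signals: list[EqtlSignal] = []
    for i, prim in enumerate(primaries):
        if prim is None or not sig_mask[i]:
            continue
        prim.q = float(q[i])
        signals.append(prim)
        if max_conditional > 0:
            feat = expr.features.iloc[i]
            mask = cis_mask(
                panel.variants, feat["chrom"], feat["start"], feat["end"], cis_window
            )
            g = panel.dosages[:, mask]
            signals.extend(
                conditional_scan(
                    expr.values[i], g, ids[mask], covariates, engine, prim,
                    p_cutoff=cutoff, max_conditional=max_conditional, **meff_kwargs,
                )
            )
    return signals, features


def signals_table(signals: list[EqtlSignal]) -> pd.DataFrame:
    rows = []
    for s in signals:
        j = s.scan.lead_index
        rows.append(
            {
                "feature_id": s.feature_id,
                "level": s.level,
                "signal_rank": s.signal_rank,
                "lead_id": s.lead_id,
                "beta": float(s.scan.beta[j]),
                "se": float(s.scan.se[j]),
                "p": float(s.scan.p[j]),
                "corrected_p": s.corrected_p,
                "q": s.q,
                "conditioned_on": ",".join(s.conditioned_on),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "level", "signal_rank", "lead_id", "beta", "se",
            "p", "corrected_p", "q", "conditioned_on",
        ],
    )
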