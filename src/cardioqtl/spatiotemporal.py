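"""Genotype-by-context interaction analysis and the shared / specific /
associated classification of eQTL signals.

Each significant signal's lead variant is tested for a genotype x context
interaction in the same kinship-aware LMM as the main scan. Interaction
p-values are Bonferroni-corrected per context (family = all signals tested
for that context). Signals with a significant interaction are then refit in
two sample subsets — for binary contexts, the tested context versus all
other samples; for cell types, the top versus bottom quartile of the
deconvoluted fraction — and the four-scenario decision table assigns the
label:

  A significant, B not                      -> specific
  B significant only                        -> not_classified
  both significant, |beta_A| > |beta_B|     -> associated
  both significant, |beta_B| >= |beta_A|    -> not_classified

Subset p-values are BH-corrected across all (signal, context, subset)
refits in the run before the table is applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .lmm import LMMEngine
from .types import ContextDefinition, EqtlSignal, GenotypePanel, InteractionResult

MIN_SUBSET = 30
LABELS = ("shared", "specific", "associated", "not_classified")


def fit_interaction_lmm(
    y: np.ndarray,
    x: np.ndarray,
    z: np.ndarray,
    covariates: np.ndarray | None,
    kinship: np.ndarray | None,
) -> dict:
    """Interaction LMM for one lead variant and one context.

    x is standardized genotype; z the context indicator or cell fraction.
    Returns main effects, the interaction beta3 with its Wald p, fitted
    jointly on top of the covariates with variance components from the
    covariates(+z)-only null.
    """
    z = np.asarray(z, dtype=float)
    if np.all(z == z[0]):
        raise ValueError("context is constant across samples")
    x = np.asarray(x, dtype=float)
    if x.std() > 0:
        x = (x - x.mean()) / x.std()
    engine = LMMEngine(kinship, n=len(x))
    cov = z[:, None] if covariates is None else np.column_stack([covariates, z])
    terms = np.column_stack([x, x * z])
    coef, se, p = engine.fit_terms(y, cov, terms)
    return {
        "beta1": float(coef[0]),
        "beta3": float(coef[1]),
        "se3": float(se[1]),
        "p_interaction": float(p[1]),
    }


def subset_refit(
    y: np.ndarray,
    x: np.ndarray,
    covariates: np.ndarray | None,
    kinship: np.ndarray | None,
    idx: np.ndarray,
) -> tuple[float, float]:
    """Standard single-variant LMM fit within a sample subset -> (beta, p)."""
    idx = np.asarray(idx)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if len(idx) < MIN_SUBSET:
        return np.nan, np.nan
    ys = np.asarray(y, dtype=float)[idx]
    xs = np.asarray(x, dtype=float)[idx]
    if xs.std() == 0:
        return np.nan, np.nan
    ks = kinship[np.ix_(idx, idx)] if kinship is not None else None
    cov = None if covariates is None else _clean_covariates(covariates[idx])
    engine = LMMEngine(ks, n=len(idx))
    null = engine.fit_null(ys, cov)
    beta, se, p = engine.scan(null, xs[:, None])
    return float(beta[0]), float(p[0])


def _clean_covariates(cov: np.ndarray) -> np.ndarray | None:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    keep = cov.std(axis=0) > 0
    if not keep.any():
        return None
    return cov[:, keep]


def four_scenario_label(q_a: float, beta_a: float, q_b: float, beta_b: float,
                        alpha: float = 0.05) -> str:
    """Decision table on the two subset refits (A = tested context)."""
    sig_a = np.isfinite(q_a) and q_a < alpha
    sig_b = np.isfinite(q_b) and q_b < alpha
    if sig_a and not sig_b:
        return "specific"
    if sig_b and not sig_a:
        return "not_classified"
    if sig_a and sig_b:
        return "associated" if abs(beta_a) > abs(beta_b) else "not_classified"
    return "not_classified"


def quartile_sets(fraction: np.ndarray, sample_ids: list[str] | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Top and bottom quartile indices by cell fraction; ties resolved by a
    stable sort on sample id so assignment is deterministic."""
    fraction = np.asarray(fraction, dtype=float)
    n = len(fraction)
    ids = np.array(sample_ids if sample_ids is not None else [str(i) for i in range(n)])
    order = np.lexsort((ids, fraction))
    k = n // 4
    return order[-k:], order[:k]


def classify_signals(
    signals: list[EqtlSignal],
    expression_by_feature: dict[str, np.ndarray],
    panel: GenotypePanel,
    contexts: list[ContextDefinition],
    covariates: np.ndarray | None,
    kinship: np.ndarray | None,
    alpha_interaction: float = 0.05,
    alpha_subset: float = 0.05,
) -> pd.DataFrame:
    """Interaction scan + four-scenario classification for every signal x
    context. Returns the long-format classification table. A signal may
    carry labels in several contexts; exclusivity is never forced."""
    variant_col = {v: j for j, v in enumerate(panel.variants["id"])}
    results: list[InteractionResult] = []
    for ctx in contexts:
        per_ctx: list[InteractionResult] = []
        for s in signals:
            y = expression_by_feature[s.feature_id]
            x = panel.dosages[:, variant_col[s.lead_id]]
            try:
                fit = fit_interaction_lmm(y, x, ctx.values, covariates, kinship)
            except ValueError:
                continue
            per_ctx.append(
                InteractionResult(
                    signal_id=f"{s.feature_id}:{s.signal_rank}",
                    context=ctx.name,
                    context_kind=ctx.kind,
                    beta1=fit["beta1"],
                    beta2=np.nan,
                    beta3=fit["beta3"],
                    se3=fit["se3"],
                    p_interaction=fit["p_interaction"],
                )
            )
        # Bonferroni family: all signals tested for this context
        m = len(per_ctx)
        for r in per_ctx:
            r.p_bonferroni = min(1.0, r.p_interaction * m)
        results.extend(per_ctx)

    # subset refits for Bonferroni-significant interactions
    ctx_by_name = {c.name: c for c in contexts}
    refit_rows = []  # (result, which_set, beta, p)
    signal_by_id = {f"{s.feature_id}:{s.signal_rank}": s for s in signals}
    for r in results:
        if not (np.isfinite(r.p_bonferroni) and r.p_bonferroni < alpha_interaction):
            r.classification = "shared"
            continue
        ctx = ctx_by_name[r.context]
        s = signal_by_id[r.signal_id]
        y = expression_by_feature[s.feature_id]
        x = panel.dosages[:, variant_col[s.lead_id]]
        if ctx.is_binary:
            set_a = np.flatnonzero(ctx.values > 0.5)
            set_b = np.flatnonzero(ctx.values <= 0.5)
        else:
            set_a, set_b = quartile_sets(ctx.values, panel.samples)
        if min(len(set_a), len(set_b)) < MIN_SUBSET:
            warnings.warn(
                f"{r.signal_id} x {r.context}: subset below {MIN_SUBSET} samples"
            )
            r.classification = "not_classified"
            continue
        beta_a, p_a = subset_refit(y, x, covariates, kinship, set_a)
        beta_b, p_b = subset_refit(y, x, covariates, kinship, set_b)
        r.beta_a, r.beta_b = beta_a, beta_b
        refit_rows.append((r, p_a, p_b))

    # BH across all follow-up refits in the run
    if refit_rows:
        ps = np.array([[p_a, p_b] for _, p_a, p_b in refit_rows]).ravel()
        ok = np.isfinite(ps)
        qs = np.full_like(ps, np.nan)
        if ok.any():
            _, qv, _, _ = multipletests(ps[ok], method="fdr_bh")
            qs[ok] = qv
        qs = qs.reshape(-1, 2)
        for (r, _, _), (q_a, q_b) in zip(refit_rows, qs):
            r.q_a, r.q_b = float(q_a), float(q_b)
            r.classification = four_scenario_label(
                r.q_a, r.beta_a, r.q_b, r.beta_b, alpha=alpha_subset
            )

    return pd.DataFrame(
        [
            {
                "signal_id": r.signal_id,
                "context": r.context,
                "context_kind": r.context_kind,
                "beta3": r.beta3,
                "p_interaction": r.p_interaction,
                "p_bonferroni": r.p_bonferroni,
                "beta_a": r.beta_a,
                "q_a": r.q_a,
                "beta_b": r.beta_b,
                "q_b": r.q_b,
                "classification": r.classification,
            }
            for r in results
        ]
    )
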