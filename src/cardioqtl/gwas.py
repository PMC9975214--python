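"""GWAS-eQTL colocalization, clustering of colocalized signals into
independent GWAS loci, credible-set selection, the comparison against
GWAS-only fine-mapping, context-enrichment sweeps, and LD-based novelty
classification against a GWAS catalog.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bayes import ABFConfig, credible_set_99, finemap_ppa, wakefield_log_abf
from .ld import LDPanel
from .types import ColocResult, CredibleSet, EqtlSignal, GWASSummaryStats

GWAS_SIGNIFICANT = 5e-8
PROXIMITY = 500_000


# ------------------------------------------------------------ testable pairs


def select_testable_pairs(
    gwas: GWASSummaryStats,
    signals: list[EqtlSignal],
    features: pd.DataFrame,
) -> list[tuple[EqtlSignal, str]]:
    """Signal/trait pairs eligible for colocalization: the signal's feature
    lies within 500 kb of a genome-wide significant GWAS variant
    (p < 5e-8, strict). Returns (signal, trait) pairs."""
    tab = gwas.table
    sig_rows = tab[tab["pval"] < GWAS_SIGNIFICANT]
    if sig_rows.empty:
        return []
    feat = features.set_index("id")
    out = []
    for s in signals:
        f = feat.loc[s.feature_id]
        on_c = sig_rows[sig_rows["chrom"] == f["chrom"]]
        if on_c.empty:
            continue
        pos = on_c["pos"].to_numpy()
        if np.any((pos >= f["start"] - PROXIMITY) & (pos <= f["end"] + PROXIMITY)):
            out.append((s, gwas.trait))
    return out


def coloc_signal_with_gwas(
    signal: EqtlSignal, gwas: GWASSummaryStats, config: ABFConfig | None = None
) -> ColocResult:
    """Colocalize one eQTL signal (conditioned stats for conditional
    signals) with the GWAS summary statistics on the shared variant list."""
    config = config or ABFConfig()
    tab = gwas.table.set_index("id")
    common = [v for v in signal.scan.variant_ids if v in tab.index]
    if len(common) < 2:
        warnings.warn("fewer than 2 shared variants for GWAS coloc")
        return ColocResult(pp=np.full(5, np.nan), n_variants=len(common), label="not_resolved")
    idx = {v: j for j, v in enumerate(signal.scan.variant_ids)}
    i1 = np.array([idx[v] for v in common])
    sub = tab.loc[common]
    from .bayes import coloc_summary_pair

    res = coloc_summary_pair(
        signal.scan.beta[i1],
        signal.scan.se[i1],
        sub["beta"].to_numpy(),
        sub["se"].to_numpy(),
        variant_ids=np.asarray(common),
        config=config,
    )
    res.signal_pair = ((signal.feature_id, signal.signal_rank), (gwas.trait, 0))
    return res


# ----------------------------------------------------------------- clusters


@dataclass
class GWASLocusCluster:
    cluster_id: int
    members: list[dict] = field(default_factory=list)  # trait, signal, pp_h4, lead, credible_set
    selected: CredibleSet | None = None
    novelty: str = ""

    @property
    def lead_snps(self) -> list[str]:
        return [m["lead"] for m in self.members]


def cluster_gwas_signals(
    colocalized: list[dict],
    ld: LDPanel,
    d_prime_min: float = 0.8,
    seed: int = 0,
) -> list[GWASLocusCluster]:
    """Cluster colocalizations into independent GWAS loci.

    ``colocalized`` rows need keys {trait, signal, lead, pp_h4, credible_set}.
    Nodes are colocalization rows; edges join pairs sharing a lead SNP or
    with leads in high LD (D' > ``d_prime_min``); communities come from
    seeded Louvain modularity maximization. Leads missing from the LD panel
    conservatively contribute no LD edges.
    """
    # drop exact duplicate rows so cluster count is invariant to duplication
    seen = set()
    rows = []
    for r in colocalized:
        key = (r["trait"], r["signal"], r["lead"])
        if key not in seen:
            seen.add(key)
            rows.append(r)
    g = nx.Graph()
    g.add_nodes_from(range(len(rows)))
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            li, lj = rows[i]["lead"], rows[j]["lead"]
            if li == lj:
                g.add_edge(i, j)
                continue
            if li in ld and lj in ld:
                dp = ld.d_prime(li, lj)
                if np.isfinite(dp) and dp > d_prime_min:
                    g.add_edge(i, j)
            else:
                warnings.warn(f"lead SNP missing from LD panel: {li} or {lj}")
    communities = nx.community.louvain_communities(g, seed=seed, resolution=1.0)
    clusters = []
    for cid, comm in enumerate(sorted(communities, key=lambda c: min(c))):
        clusters.append(
            GWASLocusCluster(cluster_id=cid, members=[rows[i] for i in sorted(comm)])
        )
    return clusters


def select_credible_set(cluster: GWASLocusCluster) -> CredibleSet:
    """Minimal-cardinality member credible set; ties by highest lead PPA,
    remaining ties lexicographic on the lead variant id."""
    sets = [m["credible_set"] for m in cluster.members if m.get("credible_set") is not None]
    if not sets:
        raise ValueError("cluster has no member credible sets")
    best = sorted(sets, key=lambda cs: (cs.size, -cs.lead_ppa, cs.lead))[0]
    cluster.selected = best
    return best


# ------------------------------------------------- coloc vs GWAS-only sets


def coloc_credible_set(res: ColocResult) -> CredibleSet:
    """99% credible set from the per-variant posteriors under H4."""
    if res.h4_ppa is None or res.variant_ids is None:
        raise ValueError("colocalization result carries no per-variant posteriors")
    return credible_set_99(res.h4_ppa, res.variant_ids)


def gwas_only_credible_set(
    gwas: GWASSummaryStats,
    variant_ids: np.ndarray,
    config: ABFConfig | None = None,
) -> CredibleSet:
    """Standard single-trait fine-mapping of the GWAS signal alone."""
    tab = gwas.table.set_index("id").loc[list(variant_ids)]
    labf = wakefield_log_abf(tab["beta"].to_numpy(), tab["se"].to_numpy(), config)
    ppa = finemap_ppa(labf)
    return credible_set_99(ppa, np.asarray(variant_ids), tab["pos"].to_numpy())


def compare_with_gwas_only_finemap(pairs: list[tuple[CredibleSet, CredibleSet]]) -> dict:
    """Paired comparison of (coloc-based, GWAS-only) credible sets per locus:
    set sizes and lead PPAs, with paired t-tests (one-sided: coloc sets
    smaller, coloc lead PPA larger)."""
    sizes = np.array([(c.size, g.size) for c, g in pairs], dtype=float)
    ppas = np.array([(c.lead_ppa, g.lead_ppa) for c, g in pairs], dtype=float)

    def _paired_p(a, b, alternative):
        if np.allclose(a, b):
            return 1.0
        return float(stats.ttest_rel(a, b, alternative=alternative).pvalue)

    return {
        "n_loci": len(pairs),
        "mean_size_coloc": float(sizes[:, 0].mean()),
        "mean_size_gwas_only": float(sizes[:, 1].mean()),
        "p_size_smaller": _paired_p(sizes[:, 0], sizes[:, 1], "less"),
        "mean_lead_ppa_coloc": float(ppas[:, 0].mean()),
        "mean_lead_ppa_gwas_only": float(ppas[:, 1].mean()),
        "p_ppa_larger": _paired_p(ppas[:, 0], ppas[:, 1], "greater"),
        "table": pd.DataFrame(
            {
                "size_coloc": sizes[:, 0].astype(int),
                "size_gwas_only": sizes[:, 1].astype(int),
                "lead_ppa_coloc": ppas[:, 0],
                "lead_ppa_gwas_only": ppas[:, 1],
            }
        ),
    }


# ------------------------------------------------------- context enrichment


def fisher_or_p(table: np.ndarray) -> tuple[float, float, float]:
    """(odds ratio, Haldane-corrected OR, two-sided exact p) for a 2x2 table."""
    t = np.asarray(table, dtype=float)
    odds, p = stats.fisher_exact(t)
    th = t + 0.5
    haldane = (th[0, 0] * th[1, 1]) / (th[0, 1] * th[1, 0])
    return float(odds), float(haldane), float(p)


def context_enrichment_sweep(
    coloc_pp_h4: np.ndarray,
    context_flags: dict[str, np.ndarray],
    trait: str,
    thresholds: np.ndarray | None = None,
    fdr_flag_threshold: float = 0.1,
    flag_at: float = 0.8,
) -> pd.DataFrame:
    """Fisher enrichment of context-associated signals among colocalizing
    signals over a PP-H4 threshold grid (0-0.95 in 0.05 steps).

    ``coloc_pp_h4``: per-signal max PP-H4 with the trait. ``context_flags``:
    per context, a boolean per-signal vector of context association. BH is
    applied across all tests for the trait; a context is flagged when its
    adjusted p < ``fdr_flag_threshold`` at the ``flag_at`` threshold.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 0.951, 0.05), 2)
    pp = np.asarray(coloc_pp_h4, dtype=float)
    rows = []
    for ctx, flags in context_flags.items():
        flags = np.asarray(flags, dtype=bool)
        for t in thresholds:
            coloc = pp > t
            table = np.array(
                [
                    [np.sum(flags & coloc), np.sum(flags & ~coloc)],
                    [np.sum(~flags & coloc), np.sum(~flags & ~coloc)],
                ]
            )
            degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
            odds, haldane, p = fisher_or_p(table)
            rows.append(
                {
                    "trait": trait,
                    "context": ctx,
                    "threshold": float(t),
                    "odds_ratio": np.nan if degenerate else odds,
                    "odds_ratio_haldane": haldane,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["q"] = q
    at = out["threshold"] == flag_at
    flagged = out.loc[at & (out["q"] < fdr_flag_threshold), "context"].unique()
    out["flagged"] = out["context"].isin(flagged) & at
    return out


# ----------------------------------------------------------- catalog labels


def classify_vs_catalog(
    lead_snp: str,
    catalog: pd.DataFrame,
    trait: str,
    ld: LDPanel,
    high_ld: float = 0.8,
    low_ld: float = 0.2,
) -> str:
    """Novelty of a fine-mapped lead versus same-trait catalog index SNPs:
    index_match / high_LD (r2 > 0.8) / low_moderate_LD (0.2 <= r2 <= 0.8)
    / novel. A lead absent from the LD panel is 'novel_unresolved'."""
    idx = catalog.loc[catalog["trait"] == trait, "index_snp"]
    if (idx == lead_snp).any():
        return "index_match"
    if lead_snp not in ld:
        return "novel_unresolved"
    r2s = [ld.r2(lead_snp, s) for s in idx if s in ld]
    r2s = [r for r in r2s if np.isfinite(r)]
    if not r2s:
        return "novel"
    best = max(r2s)
    if best > high_ld:
        return "high_LD"
    if low_ld <= best <= high_ld:
        return "low_moderate_LD"
    return "novel"
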