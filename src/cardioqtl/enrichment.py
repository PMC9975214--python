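"""Annotation, multigenic, antisense, and chromatin-state enrichment
statistics over fine-mapped eQTL and GWAS variants.

Variants enter enrichment sets only with PPA above 0.01. Annotation
intervals are held 0-based half-open internally; variant positions are
1-based (VCF convention). Promoters are the 2000 bp upstream of the TSS,
strand-aware; splice windows extend into the intron from the exon
boundary (short = 5 nt, long = 100 bp).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bayes import ABFConfig, best_pair_coloc
from .gwas import fisher_or_p
from .types import EqtlSignal

PPA_MIN = 0.01
PROMOTER_BP = 2000
SPLICE_SHORT = 5
SPLICE_LONG = 100

# exon wins on exon/intron boundary ties; higher rank wins
CLASS_PRECEDENCE = [
    "intergenic", "intron", "exon", "utr",
    "splice_donor_long", "splice_acceptor_long",
    "splice_donor_short", "splice_acceptor_short", "promoter",
]


# -------------------------------------------------------------- annotations


def build_gene_annotations(genes: pd.DataFrame, exons: pd.DataFrame | None = None
                           ) -> pd.DataFrame:
    """Interval table (0-based half-open) for promoter / exon / intron /
    splice windows from a gene model. ``genes`` needs chrom/start/end/strand
    (1-based inclusive coordinates); ``exons`` needs gene_id/start/end."""
    rows = []
    for _, g in genes.iterrows():
        if g["strand"] == "+":
            p0, p1 = g["start"] - 1 - PROMOTER_BP, g["start"] - 1
        else:
            p0, p1 = g["end"], g["end"] + PROMOTER_BP
        rows.append({"chrom": g["chrom"], "start": max(p0, 0), "end": p1, "cls": "promoter"})
        gene_exons = (
            exons[exons["gene_id"] == g["id"]] if exons is not None else pd.DataFrame()
        )
        if gene_exons.empty:
            rows.append(
                {"chrom": g["chrom"], "start": g["start"] - 1, "end": g["end"], "cls": "exon"}
            )
            continue
        ex = gene_exons.sort_values("start")
        for _, e in ex.iterrows():
            rows.append(
                {"chrom": g["chrom"], "start": e["start"] - 1, "end": e["end"], "cls": "exon"}
            )
        bounds = list(zip(ex["end"].to_numpy()[:-1], ex["start"].to_numpy()[1:]))
        for left_end, right_start in bounds:
            rows.append(
                {"chrom": g["chrom"], "start": left_end, "end": right_start - 1, "cls": "intron"}
            )
            for span, tag in ((SPLICE_SHORT, "short"), (SPLICE_LONG, "long")):
                rows.append(
                    {"chrom": g["chrom"], "start": left_end,
                     "end": min(left_end + span, right_start - 1),
                     "cls": f"splice_donor_{tag}"}
                )
                rows.append(
                    {"chrom": g["chrom"], "start": max(right_start - 1 - span, left_end),
                     "end": right_start - 1, "cls": f"splice_acceptor_{tag}"}
                )
    return pd.DataFrame(rows)


def annotate_variants(variants: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Label each variant with every annotation class it overlaps.

    ``variants`` needs id/chrom/pos (1-based); ``annotations`` needs
    chrom/start/end/cls (0-based half-open). Variants on chromosomes absent
    from the annotation table are skipped with a warning; the result is one
    row per remaining variant with a set-valued 'classes' column plus a
    deterministic 'top_class' by the precedence list.
    """
    trees: dict = {}
    for c, grp in annotations.groupby("chrom"):
        tree = IntervalTree()
        for _, r in grp.iterrows():
            if r["end"] > r["start"]:
                tree.addi(int(r["start"]), int(r["end"]), r["cls"])
        trees[c] = tree
    known_chroms = set(trees)
    rows = []
    for _, v in variants.iterrows():
        if v["chrom"] not in known_chroms:
            warnings.warn(f"variant {v['id']}: unknown chromosome {v['chrom']}; skipped")
            continue
        hits = {iv.data for iv in trees[v["chrom"]].at(int(v["pos"]) - 1)}
        if not hits:
            hits = {"intergenic"}
        rows.append({"id": v["id"], "classes": frozenset(sorted(hits))})
    out = pd.DataFrame(rows, columns=["id", "classes"])
    rank = {c: i for i, c in enumerate(CLASS_PRECEDENCE)}
    out["top_class"] = [
        max(cls, key=lambda c: rank.get(c, -1)) for cls in out["classes"]
    ]
    return out


# ----------------------------------------------------- gene vs isoform test


def fisher_with_ci(table: np.ndarray) -> dict:
    """Odds ratio, 95% CI on log2 OR (normal approximation on the Haldane-
    corrected table), and the exact two-sided p."""
    odds, haldane, p = fisher_or_p(table)
    th = np.asarray(table, dtype=float) + 0.5
    se_log = np.sqrt((1.0 / th).sum())
    log_or = np.log(haldane)
    lo, hi = log_or - 1.96 * se_log, log_or + 1.96 * se_log
    return {
        "odds_ratio": odds,
        "log2_or": np.log2(haldane),
        "ci_low_log2": lo / np.log(2),
        "ci_high_log2": hi / np.log(2),
        "p": p,
    }


def class_contrast(
    classes_a: list[frozenset], classes_b: list[frozenset],
    label_a: str = "a", label_b: str = "b",
) -> pd.DataFrame:
    """Per-annotation-class Fisher contrast of two variant groups, BH across
    classes. Generic worker for the gene-vs-isoform, correlated-vs-
    anticorrelated, and shared-vs-distinct antisense contrasts."""
    all_classes = sorted(set().union(*classes_a, *classes_b)) if (classes_a or classes_b) else []
    rows = []
    for cls in all_classes:
        a_in = sum(cls in c for c in classes_a)
        b_in = sum(cls in c for c in classes_b)
        table = np.array(
            [[a_in, len(classes_a) - a_in], [b_in, len(classes_b) - b_in]]
        )
        if table.sum() == 0:
            continue
        res = fisher_with_ci(table)
        res["cls"] = cls
        res[f"n_{label_a}"] = a_in
        res[f"n_{label_b}"] = b_in
        rows.append(res)
    out = pd.DataFrame(rows)
    if not out.empty:
        _, q, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
        out["q"] = q
    return out


def gene_vs_isoform_enrichment(fine_mapped: pd.DataFrame) -> pd.DataFrame:
    """Per-class enrichment of gene-level versus isoform-level fine-mapped
    variants (PPA > 0.01 upstream). ``fine_mapped`` needs level + classes."""
    genes = list(fine_mapped.loc[fine_mapped["level"] == "gene", "classes"])
    isos = list(fine_mapped.loc[fine_mapped["level"] == "isoform", "classes"])
    if not genes or not isos:
        raise ValueError("need fine-mapped variants at both levels")
    return class_contrast(genes, isos, "gene", "isoform")


# ------------------------------------------------------------- multigenic


def multigenic_sharing(
    signals: list[EqtlSignal],
    features: pd.DataFrame,
    config: ABFConfig | None = None,
    window: int = 500_000,
    pp_h4_min: float = 0.8,
) -> pd.DataFrame:
    """Shared-signal groups: colocalize all signal pairs from different genes
    whose features lie within 500 kb, connect pairs with PP-H4 > 0.8, and
    report connected components with their distinct-gene counts."""
    config = config or ABFConfig()
    feat = features.set_index("id")
    by_feature: dict[str, list[EqtlSignal]] = {}
    for s in signals:
        by_feature.setdefault(s.feature_id, []).append(s)
    ids = list(by_feature)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(len(ids)):
        fi = feat.loc[ids[i]]
        for j in range(i + 1, len(ids)):
            fj = feat.loc[ids[j]]
            if fi.get("gene_id", ids[i]) == fj.get("gene_id", ids[j]):
                continue
            if fi["chrom"] != fj["chrom"]:
                continue
            if min(abs(fi["start"] - fj["end"]), abs(fj["start"] - fi["end"]),
                   abs(fi["start"] - fj["start"]), abs(fi["end"] - fj["end"])) > window:
                continue
            res = best_pair_coloc(by_feature[ids[i]], by_feature[ids[j]], config)
            if np.isfinite(res.pp_h4) and res.pp_h4 > pp_h4_min:
                g.add_edge(ids[i], ids[j], pp_h4=res.pp_h4)
    rows = []
    for gid, comp in enumerate(nx.connected_components(g)):
        members = sorted(comp)
        genes = {feat.loc[m].get("gene_id", m) for m in members}
        for m in members:
            rows.append({"feature_id": m, "group_id": gid, "n_genes": len(genes)})
    return pd.DataFrame(rows)


def multigenic_context_regression(
    groups: pd.DataFrame, classifications: pd.DataFrame
) -> pd.DataFrame:
    """Per context: OLS of the binary context indicator on the number of
    genes sharing the signal. ``groups`` has feature_id/n_genes;
    ``classifications`` has feature_id/context/classification."""
    merged = classifications.merge(groups, on="feature_id", how="inner")
    rows = []
    for ctx, grp in merged.groupby("context"):
        y = grp["classification"].isin(["specific", "associated"]).astype(float).to_numpy()
        x = grp["n_genes"].to_numpy(dtype=float)
        if y.sum() == 0 or len(np.unique(x)) < 2:
            rows.append({"context": ctx, "slope": np.nan, "se": np.nan, "p": np.nan})
            continue
        slope, se, p = _ols_slope(x, y)
        rows.append({"context": ctx, "slope": slope, "se": se, "p": p})
    return pd.DataFrame(rows)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    n = len(x)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ y) / sxx
    resid = y - y.mean() - slope * xc
    sigma2 = float(resid @ resid) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    t = slope / se if se > 0 else np.nan
    p = 2 * stats.t.sf(abs(t), n - 2) if np.isfinite(t) else np.nan
    return slope, float(se), float(p)


def permutation_shared_context(
    pairs: list[tuple[str, str]],
    context_labels: dict[str, set[str]],
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation Z test that colocalizing pairs share context labels.

    ``pairs``: colocalizing feature pairs; ``context_labels``: per feature,
    its set of context labels. For each context, the observed count of pairs
    where both members carry the label is compared against ``n_perm``
    permutations of the feature -> label assignment; Z converts to an upper-
    tail normal p.
    """
    rng = np.random.default_rng(seed)
    feats = sorted(context_labels)
    all_contexts = sorted(set().union(*context_labels.values())) if context_labels else []
    rows = []
    for ctx in all_contexts:
        flag = {f: (ctx in context_labels[f]) for f in feats}
        obs = sum(flag.get(a, False) and flag.get(b, False) for a, b in pairs)
        vals = np.array([flag[f] for f in feats])
        perm_counts = np.empty(n_perm)
        for k in range(n_perm):
            perm = rng.permutation(vals)
            pflag = dict(zip(feats, perm))
            perm_counts[k] = sum(
                pflag.get(a, False) and pflag.get(b, False) for a, b in pairs
            )
        sd = perm_counts.std(ddof=1)
        if sd == 0:
            rows.append({"context": ctx, "observed": obs, "z": np.nan, "p": np.nan})
            continue
        z = (obs - perm_counts.mean()) / sd
        rows.append(
            {"context": ctx, "observed": obs, "z": float(z), "p": float(stats.norm.sf(z))}
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------- antisense


def find_antisense_pairs(symbols: pd.DataFrame) -> list[tuple[str, str]]:
    """Gene / antisense pairs by the 'GENE' + 'GENE-AS1' symbol convention.

    ``symbols`` maps feature_id -> symbol. An explicit pair table can be
    passed straight to :func:`antisense_pair_enrichment` instead when symbol
    matching is too fragile."""
    sym_to_id = dict(zip(symbols["symbol"], symbols["feature_id"]))
    pairs = []
    for sym, fid in sym_to_id.items():
        partner = f"{sym}-AS1"
        if partner in sym_to_id:
            pairs.append((fid, sym_to_id[partner]))
    return sorted(pairs)


def antisense_pair_enrichment(
    antisense_pairs: list[tuple[str, str]],
    background_pairs: list[tuple[str, str]],
    shared: set[tuple[str, str]],
) -> dict:
    """Fisher test of shared-signal (PP-H4 > 0.8) proportion in antisense
    pairs versus background eGene pairs within 500 kb."""
    if not antisense_pairs:
        return {"odds_ratio": np.nan, "p": np.nan, "message": "no antisense pairs found"}

    def _n_shared(pairs):
        return sum((a, b) in shared or (b, a) in shared for a, b in pairs)

    a_sh = _n_shared(antisense_pairs)
    b_sh = _n_shared(background_pairs)
    table = np.array(
        [
            [a_sh, len(antisense_pairs) - a_sh],
            [b_sh, len(background_pairs) - b_sh],
        ]
    )
    odds, haldane, p = fisher_or_p(table)
    return {
        "odds_ratio": odds,
        "odds_ratio_haldane": haldane,
        "p": p,
        "n_antisense": len(antisense_pairs),
        "n_antisense_shared": a_sh,
        "n_background": len(background_pairs),
        "n_background_shared": b_sh,
    }


# ----------------------------------------------------- chromatin-state PPA


def chromstate_ppa_regression(
    fine_mapped: pd.DataFrame, state_annotations: pd.DataFrame, ppa_min: float = PPA_MIN
) -> pd.DataFrame:
    """Per chromatin state: OLS of the binary overlap indicator on SNP PPA,
    restricted to variants with PPA >= 0.01; BH across states."""
    fm = fine_mapped[fine_mapped["ppa"] >= ppa_min].reset_index(drop=True)
    if fm.empty:
        raise ValueError("no variants with PPA above threshold")
    states = sorted(state_annotations["cls"].unique())
    rows = []
    for st in states:
        sub = state_annotations[state_annotations["cls"] == st]
        trees: dict = {}
        for c, grp in sub.groupby("chrom"):
            tree = IntervalTree()
            for _, r in grp.iterrows():
                if r["end"] > r["start"]:
                    tree.addi(int(r["start"]), int(r["end"]), st)
            trees[c] = tree
        overlap = np.array(
            [
                bool(trees.get(v["chrom"]) and trees[v["chrom"]].at(int(v["pos"]) - 1))
                for _, v in fm.iterrows()
            ],
            dtype=float,
        )
        if overlap.sum() == 0:
            rows.append({"state": st, "slope": np.nan, "se": np.nan, "p": np.nan})
            continue
        slope, se, p = _ols_slope(fm["ppa"].to_numpy(dtype=float), overlap)
        rows.append({"state": st, "slope": slope, "se": se, "p": p})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        _, qv, _, _ = multipletests(out.loc[ok, "p"].to_numpy(), method="fdr_bh")
        out.loc[ok, "q"] = qv
    return out
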