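"""Enrichment statistics over fine-mapped variants: gene-vs-isoform
annotation contrasts, multigenic sharing and its association with
spatiotemporal regulation, antisense-pair sharing, and the chromatin-state
PPA regression on synthetic state maps."""

import numpy as np
import pandas as pd
from common import RESULTS, get_pipeline_state, get_study, step_timer

from cardioqtl.bayes import finemap_ppa, wakefield_log_abf
from cardioqtl.enrichment import (
    annotate_variants,
    antisense_pair_enrichment,
    build_gene_annotations,
    chromstate_ppa_regression,
    find_antisense_pairs,
    gene_vs_isoform_enrichment,
    multigenic_context_regression,
    multigenic_sharing,
    permutation_shared_context,
)
from cardioqtl.eqtl import map_eqtls
from cardioqtl.spatiotemporal import classify_signals


def _fine_mapped(signals, panel, level):
    """Variants with PPA > 0.01 across all signals of one level."""
    pos = panel.variants.set_index("id")[["chrom", "pos"]]
    rows = []
    for s in signals:
        ok = np.isfinite(s.scan.se) & (s.scan.se > 0)
        ppa = finemap_ppa(wakefield_log_abf(s.scan.beta[ok], s.scan.se[ok]))
        ids = s.scan.variant_ids[ok]
        for v, p in zip(ids[ppa > 0.01], ppa[ppa > 0.01]):
            rows.append({"id": v, "chrom": pos.loc[v, "chrom"],
                         "pos": pos.loc[v, "pos"], "ppa": p, "level": level,
                         "feature_id": s.feature_id})
    return pd.DataFrame(rows)


def main():
    study = get_study()
    state = get_pipeline_state(study)
    outdir = RESULTS / "enrichment"
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(0)

    with step_timer("eQTL scans"):
        gene_signals, _ = map_eqtls(state["norm"], state["panel"],
                                    state["covariates"], state["kinship"], level="gene")
        iso_signals, _ = map_eqtls(state["iso_norm"], state["panel"],
                                   state["covariates"], state["kinship"], level="isoform")

    # ---- gene vs isoform annotation contrast on synthetic gene models
    genes = state["expr"].features.rename(columns={"id": "id"})
    exon_rows = []
    for _, g in genes.iterrows():
        third = (g["end"] - g["start"]) // 3
        exon_rows.append({"gene_id": g["id"], "start": g["start"], "end": g["start"] + third})
        exon_rows.append({"gene_id": g["id"], "start": g["end"] - third, "end": g["end"]})
    ann = build_gene_annotations(genes, pd.DataFrame(exon_rows))
    fm_genes = _fine_mapped([s for s in gene_signals], state["panel"], "gene")
    fm_iso = _fine_mapped([s for s in iso_signals], state["panel"], "isoform")
    fm = pd.concat([fm_genes, fm_iso], ignore_index=True)
    labelled = annotate_variants(fm.drop_duplicates("id"), ann).set_index("id")
    fm["classes"] = [labelled.loc[v, "classes"] if v in labelled.index else frozenset()
                     for v in fm["id"]]
    contrast = gene_vs_isoform_enrichment(fm)
    contrast.to_csv(outdir / "gene_vs_isoform_annotation.tsv", sep="\t",
                    index=False, float_format="%.6g")
    print(f"annotation contrast over {len(contrast)} classes "
          f"({len(fm_genes)} gene / {len(fm_iso)} isoform fine-mapped variants)")

    # ---- multigenic sharing + spatiotemporal association
    with step_timer("multigenic sharing"):
        groups = multigenic_sharing(gene_signals, state["expr"].features)
    groups.to_csv(outdir / "multigenic_groups.tsv", sep="\t", index=False)
    multi = groups[groups["n_genes"] >= 2]
    print(f"multigenic signals: {multi['group_id'].nunique()} groups covering "
          f"{multi['feature_id'].nunique()} features")

    primaries = [s for s in gene_signals if s.signal_rank == 0]
    expr_lookup = {state["norm"].features["id"].iloc[i]: state["norm"].values[i]
                   for i in range(state["norm"].n_features)}
    with step_timer("context classification"):
        cls = classify_signals(primaries, expr_lookup, state["panel"],
                               study.contexts, state["covariates"], state["kinship"])
    cls["feature_id"] = cls["signal_id"].str.split(":").str[0]
    reg = multigenic_context_regression(groups, cls)
    reg.to_csv(outdir / "multigenic_context_regression.tsv", sep="\t",
               index=False, float_format="%.6g")
    sig_reg = reg[reg["p"] < 0.05]
    print(f"contexts with gene-count association (p < 0.05): "
          f"{sig_reg['context'].tolist()}")

    # permutation test that colocalizing pairs share context labels
    import networkx as nx

    pair_list = []
    for gid, grp in multi.groupby("group_id"):
        members = sorted(grp["feature_id"])
        pair_list.extend([(a, b) for i, a in enumerate(members) for b in members[i + 1:]])
    labels = {
        f: set(cls.loc[(cls["feature_id"] == f)
                       & cls["classification"].isin(["specific", "associated"]),
                       "context"])
        for f in cls["feature_id"].unique()
    }
    perm = permutation_shared_context(pair_list, labels, n_perm=100, seed=0)
    perm.to_csv(outdir / "shared_context_permutation.tsv", sep="\t",
                index=False, float_format="%.6g")

    # ---- antisense pairs
    symbols = pd.DataFrame({"feature_id": study.truth["gene_id"],
                            "symbol": study.truth["symbol"]})
    anti_pairs = find_antisense_pairs(symbols)
    feats = state["expr"].features.set_index("id")
    egenes = {s.feature_id for s in gene_signals}
    anti_pairs = [(a, b) for a, b in anti_pairs if a in egenes and b in egenes]
    background = []
    ids = sorted(egenes & set(feats.index))
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            fa, fb = feats.loc[a], feats.loc[b]
            if fa["chrom"] == fb["chrom"] and abs(fa["start"] - fb["start"]) <= 500_000:
                background.append((a, b))
    shared = set()
    g = nx.Graph()
    for _, r in multi.iterrows():
        g.add_node(r["feature_id"])
    for gid, grp in multi.groupby("group_id"):
        members = sorted(grp["feature_id"])
        shared |= {(a, b) for i, a in enumerate(members) for b in members[i + 1:]}
    res = antisense_pair_enrichment(anti_pairs, background, shared)
    print(f"antisense pairs sharing a signal: {res.get('n_antisense_shared', 0)} / "
          f"{res.get('n_antisense', 0)} vs background "
          f"{res.get('n_background_shared', 0)} / {res.get('n_background', 0)} "
          f"(OR = {res['odds_ratio']:.2f}, p = {res['p']:.3g})")

    # ---- chromatin-state PPA regression on synthetic states enriched
    # around planted causal variants
    truth = study.truth
    causal_pos = state["panel"].variants.set_index("id").reindex(
        truth.loc[truth["causal_variant"] != "", "causal_variant"]
    ).dropna()
    enh = pd.DataFrame({
        "chrom": causal_pos["chrom"],
        "start": causal_pos["pos"] - 200,
        "end": causal_pos["pos"] + 200,
        "cls": "enhancer",
    })
    quies_pos = rng.integers(1_000_000, 3_000_000, 200)
    quies = pd.DataFrame({"chrom": "chr1", "start": quies_pos,
                          "end": quies_pos + 400, "cls": "quiescent"})
    states = pd.concat([enh, quies], ignore_index=True)
    chrom_reg = chromstate_ppa_regression(fm, states)
    chrom_reg.to_csv(outdir / "chromstate_regression.tsv", sep="\t",
                     index=False, float_format="%.6g")
    print("chromatin-state PPA regression:")
    print(chrom_reg.to_string(index=False))


if __name__ == "__main__":
    main()
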