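"""Annotation assignment, Fisher contrasts, multigenic sharing, the
context regressions and permutation test, antisense pairing, and the
chromatin-state PPA regression — against interval scans, hypergeometric
tail sums, and closed-form OLS."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardioqtl.enrichment import (
    annotate_variants,
    antisense_pair_enrichment,
    build_gene_annotations,
    chromstate_ppa_regression,
    class_contrast,
    find_antisense_pairs,
    fisher_with_ci,
    gene_vs_isoform_enrichment,
    multigenic_context_regression,
    multigenic_sharing,
    permutation_shared_context,
)
from cardioqtl.types import EqtlSignal, ScanResult
from cardioqtl.validation import hypergeom_fisher_p


def _variants(positions, chrom="chr1"):
    return pd.DataFrame(
        {"id": [f"v{p}" for p in positions], "chrom": chrom, "pos": positions}
    )


class TestAnnotation:
    GENES = pd.DataFrame(
        {"id": ["g"], "chrom": ["chr1"], "start": [10_000], "end": [20_000],
         "strand": ["+"]}
    )
    EXONS = pd.DataFrame(
        {"gene_id": ["g", "g"], "start": [10_000, 15_000], "end": [12_000, 20_000]}
    )

    def test_variant_just_upstream_of_tss_is_promoter(self):
        ann = build_gene_annotations(self.GENES, self.EXONS)
        out = annotate_variants(_variants([9_999]), ann)
        assert "promoter" in out["classes"].iloc[0]
        assert out["top_class"].iloc[0] == "promoter"

    def test_intronic_variant_near_downstream_exon_is_acceptor(self):
        ann = build_gene_annotations(self.GENES, self.EXONS)
        # intron spans (12000, 15000); 3 bp from the downstream exon start
        out = annotate_variants(_variants([14_997]), ann)
        classes = out["classes"].iloc[0]
        assert "splice_acceptor_short" in classes and "splice_acceptor_long" in classes
        assert "intron" in classes

    def test_matches_brute_force_interval_scan(self):
        rng = np.random.default_rng(0)
        intervals = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": rng.integers(0, 10_000, 40),
                "cls": rng.choice(["exon", "intron", "promoter"], 40),
            }
        )
        intervals["end"] = intervals["start"] + rng.integers(1, 500, 40)
        pos = rng.integers(0, 10_500, 60)
        out = annotate_variants(_variants(pos), intervals).set_index("id")
        for p in pos:
            expected = {
                r["cls"]
                for _, r in intervals.iterrows()
                if r["start"] <= p - 1 < r["end"]
            } or {"intergenic"}
            assert out.loc[f"v{p}", "classes"] == frozenset(expected)

    def test_annotation_invariant_to_interval_order(self):
        rng = np.random.default_rng(1)
        intervals = pd.DataFrame(
            {"chrom": "chr1", "start": rng.integers(0, 5000, 20),
             "cls": rng.choice(["exon", "utr"], 20)}
        )
        intervals["end"] = intervals["start"] + 200
        pos = rng.integers(0, 5200, 30)
        a = annotate_variants(_variants(pos), intervals)
        b = annotate_variants(_variants(pos), intervals.iloc[::-1])
        assert a.equals(b)

    def test_unknown_chromosome_skipped(self):
        intervals = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [100], "cls": ["exon"]}
        )
        with pytest.warns(UserWarning, match="unknown chromosome"):
            out = annotate_variants(_variants([50], chrom="chrZ"), intervals)
        assert out.empty


class TestFisherContrasts:
    def test_cross_product_odds_ratio(self):
        res = fisher_with_ci(np.array([[30, 10], [10, 30]]))
        assert res["odds_ratio"] == pytest.approx(9.0)
        assert res["p"] == pytest.approx(
            hypergeom_fisher_p(np.array([[30, 10], [10, 30]])), abs=1e-12
        )

    def test_identical_distributions_are_null(self):
        classes = [frozenset(["exon"])] * 20 + [frozenset(["intron"])] * 20
        out = class_contrast(classes, classes)
        assert np.allclose(out["odds_ratio"].astype(float), 1.0)
        assert (out["q"] > 0.5).all()

    def test_planted_splice_enrichment_points_at_isoforms(self):
        rng = np.random.default_rng(2)
        gene_classes = [
            frozenset(["splice_donor_short"]) if rng.random() < 0.05
            else frozenset(["intergenic"])
            for _ in range(400)
        ]
        iso_classes = [
            frozenset(["splice_donor_short"]) if rng.random() < 0.25
            else frozenset(["intron"])
            for _ in range(400)
        ]
        fm = pd.DataFrame(
            {"level": ["gene"] * 400 + ["isoform"] * 400,
             "classes": gene_classes + iso_classes}
        )
        out = gene_vs_isoform_enrichment(fm).set_index("cls")
        splice = out.loc["splice_donor_short"]
        assert splice["odds_ratio"] < 1 and splice["q"] < 0.05
        inter = out.loc["intergenic"]
        assert inter["odds_ratio"] > 1 and inter["q"] < 0.05


def _signal_at(fid, variant_ids, beta, se):
    ids = np.asarray(variant_ids)
    return EqtlSignal(
        feature_id=fid, level="gene", signal_rank=0, lead_id=str(ids[np.argmax(np.abs(beta / se))]),
        scan=ScanResult(ids, np.asarray(beta, dtype=float), np.asarray(se, dtype=float),
                        np.full(len(ids), 0.5)),
        corrected_p=0.0,
    )


class TestMultigenic:
    def _features(self, n, spacing=100_000):
        return pd.DataFrame(
            {"id": [f"g{i}" for i in range(n)],
             "gene_id": [f"g{i}" for i in range(n)],
             "chrom": "chr1",
             "start": 1_000_000 + spacing * np.arange(n)}
        ).assign(end=lambda d: d["start"] + 10_000)

    def test_three_genes_sharing_a_causal_variant_form_one_group(self):
        rng = np.random.default_rng(3)
        m = 15
        ids = [f"v{j}" for j in range(m)]
        se = np.full(m, 0.05)
        shared = rng.normal(0, 1, m) * se
        shared[7] = 0.8
        signals = [
            _signal_at(f"g{i}", ids, shared + rng.normal(0, 0.01, m), se)
            for i in range(3)
        ]
        groups = multigenic_sharing(signals, self._features(3))
        assert len(groups) == 3
        assert (groups["n_genes"] == 3).all()
        assert groups["group_id"].nunique() == 1

    def test_unrelated_signals_stay_singletons(self):
        rng = np.random.default_rng(4)
        m = 15
        ids = [f"v{j}" for j in range(m)]
        se = np.full(m, 0.05)
        signals = []
        for i in range(3):
            b = rng.normal(0, 1, m) * se
            b[2 + 5 * i] = 0.8  # distinct causal variants
            signals.append(_signal_at(f"g{i}", ids, b, se))
        groups = multigenic_sharing(signals, self._features(3))
        assert (groups["n_genes"] == 1).all()

    def test_context_regression_matches_closed_form(self):
        counts = np.array([1, 1, 2, 2, 3, 3, 4, 4, 5, 5], dtype=float)
        flags = np.array([0, 0, 0, 1, 0, 1, 1, 1, 1, 1], dtype=float)
        groups = pd.DataFrame({"feature_id": [f"g{i}" for i in range(10)], "n_genes": counts})
        cls = pd.DataFrame(
            {"feature_id": [f"g{i}" for i in range(10)], "context": "adult",
             "classification": np.where(flags == 1, "specific", "shared")}
        )
        out = multigenic_context_regression(groups, cls)
        lr = stats.linregress(counts, flags)
        assert out["slope"].iloc[0] == pytest.approx(lr.slope, abs=1e-12)
        assert out["se"].iloc[0] == pytest.approx(lr.stderr, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(lr.pvalue, abs=1e-12)

    def test_permutation_detects_aligned_labels(self):
        feats = [f"g{i}" for i in range(40)]
        pairs = [(feats[i], feats[i + 1]) for i in range(0, 20, 2)]
        labels = {f: ({"adult"} if i < 20 else set()) for i, f in enumerate(feats)}
        out = permutation_shared_context(pairs, labels, n_perm=100, seed=0)
        row = out[out["context"] == "adult"].iloc[0]
        assert row["z"] > 2 and row["p"] < 0.01

    def test_permutation_null_and_determinism(self):
        rng = np.random.default_rng(5)
        feats = [f"g{i}" for i in range(40)]
        zs = []
        for rep in range(15):
            labels = {f: ({"adult"} if rng.random() < 0.4 else set()) for f in feats}
            pairs = [tuple(rng.choice(feats, 2, replace=False)) for _ in range(12)]
            out = permutation_shared_context(pairs, labels, n_perm=100, seed=rep)
            z = out[out["context"] == "adult"]["z"].iloc[0]
            if np.isfinite(z):
                zs.append(abs(z) < 2)
        assert np.mean(zs) >= 0.8
        a = permutation_shared_context(pairs, labels, n_perm=50, seed=42)
        b = permutation_shared_context(pairs, labels, n_perm=50, seed=42)
        assert a.equals(b)


class TestAntisense:
    def test_symbol_convention(self):
        symbols = pd.DataFrame(
            {"feature_id": ["f1", "f2", "f3", "f4"],
             "symbol": ["PAX8", "PAX8-AS1", "IRF1", "IRF1-AS2"]}
        )
        assert find_antisense_pairs(symbols) == [("f1", "f2")]

    def test_planted_sharing_enrichment(self):
        rng = np.random.default_rng(6)
        anti = [(f"a{i}", f"b{i}") for i in range(20)]
        bg = [(f"x{i}", f"y{i}") for i in range(300)]
        shared = {p for p in anti if rng.random() < 0.6}
        shared |= {p for p in bg if rng.random() < 0.05}
        res = antisense_pair_enrichment(anti, bg, shared)
        assert res["odds_ratio"] > 1 and res["p"] < 0.01

    def test_no_pairs_reports_na(self):
        res = antisense_pair_enrichment([], [("x", "y")], set())
        assert np.isnan(res["odds_ratio"]) and "message" in res


class TestChromatinStates:
    def _states(self):
        return pd.DataFrame(
            {"chrom": "chr1", "start": [0, 5_000], "end": [1_000, 6_000],
             "cls": ["enhancer", "tss"]}
        )

    def test_regression_matches_closed_form(self):
        ppa = np.linspace(0.01, 0.9, 12)
        pos = np.where(ppa > 0.4, 500, 8_000)  # high-PPA variants in the enhancer
        fm = pd.DataFrame(
            {"id": [f"v{i}" for i in range(12)], "chrom": "chr1", "pos": pos,
             "ppa": ppa}
        )
        out = chromstate_ppa_regression(fm, self._states()).set_index("state")
        overlap = (pos == 500).astype(float)
        lr = stats.linregress(ppa, overlap)
        assert out.loc["enhancer", "slope"] == pytest.approx(lr.slope, abs=1e-12)
        assert out.loc["enhancer", "p"] == pytest.approx(lr.pvalue, abs=1e-12)

    def test_shuffled_ppa_is_null(self):
        rng = np.random.default_rng(7)
        cover = 0
        for _ in range(20):
            ppa = rng.uniform(0.01, 1.0, 60)
            pos = rng.choice([500, 8_000], 60)
            fm = pd.DataFrame(
                {"id": [f"v{i}" for i in range(60)], "chrom": "chr1",
                 "pos": pos, "ppa": rng.permutation(ppa)}
            )
            out = chromstate_ppa_regression(fm, self._states()).set_index("state")
            s, se = out.loc["enhancer", "slope"], out.loc["enhancer", "se"]
            cover += int(abs(s) < 1.96 * se)
        assert cover >= 18  # slope CI covers 0 in >= 90% of replicates


class TestMultigenicOnPlantedCohort:
    def test_planted_multigenic_groups_recovered(self, small_study, mapped_small_study):
        """Genes planted on one shared causal variant are grouped together
        by pairwise colocalization of their mapped signals."""
        signals = mapped_small_study["signals"]
        truth = small_study.truth
        feats = mapped_small_study["expr"].features
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            groups = multigenic_sharing(signals, feats)
        planted = truth[truth["multigenic_group"] >= 0]
        mapped_ids = {s.feature_id for s in signals}
        for gid, grp in planted.groupby("multigenic_group"):
            members = [g for g in grp["gene_id"] if g in mapped_ids]
            if len(members) < 2:
                continue
            got = groups.set_index("feature_id").loc[members, "group_id"]
            assert got.nunique() == 1, f"planted group {gid} split"
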