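"""Expression/variant filters, rank-based normalization, kinship, genotype
PCs and the latent-factor-count sweep, checked against brute-force oracles
and boundary cases."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardioqtl import preprocess as pp
from cardioqtl.types import ExpressionMatrix, GenotypePanel


def _expr(values, state="tpm", usage=None, gene_ids=None, level="gene"):
    n_feat, n_samp = values.shape
    feats = pd.DataFrame(
        {
            "id": [f"f{i}" for i in range(n_feat)],
            "gene_id": gene_ids if gene_ids is not None else [f"f{i}" for i in range(n_feat)],
            "chrom": "chr1",
            "start": 1000,
            "end": 2000,
            "strand": "+",
            "level": level,
        }
    )
    return ExpressionMatrix(
        features=feats, samples=[f"s{j}" for j in range(n_samp)],
        values=np.asarray(values, dtype=float), state=state,
        usage=None if usage is None else np.asarray(usage, dtype=float),
    )


def _panel(dosages, pos=None, chrom="chr1"):
    d = np.asarray(dosages, dtype=float)
    m = d.shape[1]
    if pos is None:
        pos = 1000 + 100 * np.arange(m)
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypePanel(
        variants=variants, dosages=d, samples=[f"s{i}" for i in range(d.shape[0])]
    )


class TestGeneFilter:
    def test_boundary_gene_at_exactly_ten_percent_kept(self):
        vals = np.zeros((1, 20))
        vals[0, :2] = 1.0  # exactly 10% at TPM exactly 1
        out = pp.filter_expressed_genes(_expr(vals))
        assert out.n_features == 1

    def test_gene_below_tpm_threshold_everywhere_removed(self):
        vals = np.full((1, 20), 0.99)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = pp.filter_expressed_genes(_expr(vals))
        assert out.n_features == 0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        vals = rng.exponential(1.0, size=(50, 37))
        out = pp.filter_expressed_genes(_expr(vals))
        expected = [
            f"f{i}" for i in range(50)
            if sum(v >= 1.0 for v in vals[i]) >= 0.10 * 37
        ]
        assert list(out.features["id"]) == expected


class TestIsoformFilter:
    def test_usage_boundary_is_strict(self):
        # three isoforms of one gene, constant usage (0.5, 0.4, 0.1)
        tpm = np.full((3, 20), 5.0)
        usage = np.tile(np.array([[0.5], [0.4], [0.1]]), (1, 20))
        out = pp.filter_isoforms(_expr(tpm, usage=usage, gene_ids=["g"] * 3, level="isoform"))
        assert list(out.features["id"]) == ["f0", "f1"]

    def test_single_qualifying_isoform_drops_gene(self):
        tpm = np.full((2, 20), 5.0)
        usage = np.tile(np.array([[0.8], [0.05]]), (1, 20))
        out = pp.filter_isoforms(_expr(tpm, usage=usage, gene_ids=["g"] * 2, level="isoform"))
        assert out.n_features == 0

    def test_matches_brute_force_evaluation(self):
        rng = np.random.default_rng(1)
        n_iso, n_samp = 30, 25
        genes = [f"g{i // 3}" for i in range(n_iso)]
        tpm = rng.exponential(2.0, (n_iso, n_samp))
        usage = rng.dirichlet(np.ones(3), size=(10, n_samp)).transpose(0, 2, 1).reshape(n_iso, n_samp)
        out = pp.filter_isoforms(_expr(tpm, usage=usage, gene_ids=genes, level="isoform"))
        qualifying = [
            sum((tpm[i, s] >= 1.0) and (usage[i, s] > 0.10) for s in range(n_samp))
            >= 0.10 * n_samp
            for i in range(n_iso)
        ]
        counts = {}
        for i in range(n_iso):
            if qualifying[i]:
                counts[genes[i]] = counts.get(genes[i], 0) + 1
        expected = [
            f"f{i}" for i in range(n_iso)
            if qualifying[i] and counts.get(genes[i], 0) >= 2
        ]
        assert list(out.features["id"]) == expected


class TestInverseNormal:
    def test_moments_after_transform(self):
        rng = np.random.default_rng(2)
        out = pp.inverse_normal_transform(_expr(rng.exponential(1, (20, 101))))
        assert np.all(np.abs(out.values.mean(axis=1)) < 1e-8)
        assert np.all(np.abs(out.values.std(axis=1) - 1) < 1e-6)

    def test_rank_preservation(self):
        x = np.array([[3.0, 1.0, 10.0, 2.0, 7.0]])
        out = pp.inverse_normal_transform(_expr(x))
        assert np.array_equal(np.argsort(out.values[0]), np.argsort(x[0]))

    def test_median_of_odd_n_maps_to_zero(self):
        x = np.array([[5.0, 1.0, 3.0]])  # median 3 at index 2
        out = pp.inverse_normal_transform(_expr(x))
        # mean is exactly 0 by construction and the grid is symmetric
        assert abs(out.values[0, 2]) < 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        once = pp.inverse_normal_transform(_expr(rng.exponential(1, (10, 51))))
        twice = pp.inverse_normal_transform(once)
        assert np.allclose(once.values, twice.values, atol=1e-8)

    def test_constant_feature_becomes_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = pp.inverse_normal_transform(_expr(np.full((1, 10), 4.0)))
        assert np.all(out.values == 0)


class TestVariantFilter:
    def test_exact_hwe_passes(self):
        d = np.concatenate([np.zeros(25), np.full(50, 0.5), np.ones(25)])
        assert pp.hwe_chi2_p(d) == pytest.approx(1.0)

    def test_no_heterozygotes_fails_hwe(self):
        d = np.concatenate([np.zeros(50), np.ones(50)])
        # expected Aa count is 50; chi2 of 1 df is astronomically significant
        assert pp.hwe_chi2_p(d) < 1e-6

    def test_window_boundary_is_inclusive(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.4, size=(200, 2)) / 2.0
        gene = _expr(np.full((1, 200), 5.0))
        gene.features.loc[0, ["start", "end"]] = [1_000_000, 1_010_000]
        panel = _panel(d, pos=[1_510_000, 1_510_001])  # 500000 and 500001 bp past end
        out = pp.filter_variants(panel, gene)
        assert list(out.variants["id"]) == ["v0"]

    def test_filter_order_independent(self):
        """MAF / HWE / call-rate are independent criteria: the retained set
        does not depend on the order they are applied in."""
        rng = np.random.default_rng(5)
        d = rng.binomial(2, rng.uniform(0.0, 0.5, 40), size=(150, 40)) / 2.0
        d[rng.random(d.shape) < 0.005] = np.nan
        panel = _panel(d)
        joint = set(pp.filter_variants(panel, None).variants["id"])
        st_ = pp.variant_stats(panel)
        sequential = set(st_["id"])
        for crit in [
            st_["maf"] > 0.01, st_["hwe_p"] > 1e-6, st_["call_rate"] >= 0.99
        ]:
            sequential &= set(st_.loc[crit.to_numpy(), "id"])
        assert joint == sequential

    def test_per_stratum_maf_rule(self):
        d = np.zeros((100, 1))
        d[:50] = 0.5  # common in stratum A only
        panel = _panel(d)
        strata = np.array(["A"] * 50 + ["B"] * 50)
        out = pp.filter_variants(panel, None, strata=strata, hwe_min=0.0)
        assert out.n_variants == 0


class TestKinship:
    def test_duplicate_samples_look_like_self(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, rng.uniform(0.35, 0.55, 300), size=(50, 300)) / 2.0
        d = np.vstack([d, d[0]])  # duplicate the first sample
        kin = pp.compute_kinship(_panel(d))
        assert abs(kin[0, 50] - kin[0, 0]) < 0.02

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, rng.uniform(0.35, 0.55, 200), size=(40, 200)) / 2.0
        kin = pp.compute_kinship(_panel(d))
        perm = rng.permutation(40)
        kin_p = pp.compute_kinship(_panel(d[perm]))
        assert np.allclose(kin_p, kin[np.ix_(perm, perm)], atol=1e-10)

    def test_too_few_common_variants_raises(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.05, size=(30, 120)) / 2.0
        with pytest.raises(ValueError, match="AF"):
            pp.compute_kinship(_panel(d))


class TestGenotypePCs:
    def test_components_are_orthonormal(self):
        rng = np.random.default_rng(9)
        d = rng.binomial(2, rng.uniform(0.3, 0.6, 400), size=(60, 400)) / 2.0
        pcs = pp.compute_genotype_pcs(_panel(d), k=5)
        assert np.allclose(pcs.T @ pcs, np.eye(5), atol=1e-8)

    def test_pc1_separates_ancestry_clusters(self):
        rng = np.random.default_rng(10)
        f1 = rng.uniform(0.30, 0.60, 300)
        f2 = np.clip(f1 + rng.choice([-0.25, 0.25], 300), 0.05, 0.95)
        a = rng.binomial(2, f1, size=(40, 300)) / 2.0
        b = rng.binomial(2, f2, size=(40, 300)) / 2.0
        pcs = pp.compute_genotype_pcs(_panel(np.vstack([a, b])), k=2)
        labels = np.array([0] * 40 + [1] * 40)
        r = np.corrcoef(pcs[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_k_zero_gives_empty_block(self):
        rng = np.random.default_rng(11)
        d = rng.binomial(2, 0.4, size=(20, 150)) / 2.0
        assert pp.compute_genotype_pcs(_panel(d), k=0).shape == (20, 0)

    def test_k_too_large_raises(self):
        rng = np.random.default_rng(12)
        d = rng.binomial(2, 0.4, size=(10, 150)) / 2.0
        with pytest.raises(ValueError, match="exceeds"):
            pp.compute_genotype_pcs(_panel(d), k=10)


class TestLatentFactorSweep:
    def test_single_candidate_returned(self, mapped_small_study):
        best, sweep = pp.select_latent_factor_count(
            mapped_small_study["norm"],
            [3],
            mapped_small_study["panel"],
            None,
            mapped_small_study["kinship"],
            genes_per_decile=2,
        )
        assert best == 3 and len(sweep) == 1

    def test_confounded_eqtls_recovered_with_factors(self):
        """Latent confounders masking planted eQTLs: the sweep detects more
        eQTLs once enough factors are included, and selects a non-zero count."""
        rng = np.random.default_rng(13)
        n, n_genes, m = 200, 40, 10
        d = rng.binomial(2, rng.uniform(0.2, 0.5, n_genes * m), size=(n, n_genes * m)) / 2.0
        factors = rng.standard_normal((n, 5))
        vals = np.empty((n_genes, n))
        feats = []
        for g in range(n_genes):
            lam = rng.normal(0, 2.0, 5)
            x = d[:, g * m]
            xs = (x - x.mean()) / max(x.std(), 1e-9)
            vals[g] = 0.6 * xs + factors @ lam + 0.7 * rng.standard_normal(n)
            feats.append(
                {"id": f"g{g}", "gene_id": f"g{g}", "chrom": "chr1",
                 "start": 1000 + 100 * m * g, "end": 1000 + 100 * m * g + 50,
                 "strand": "+", "level": "gene"}
            )
        pos = 1000 + 100 * np.arange(n_genes * m)
        panel = _panel(d, pos=pos)
        expr = ExpressionMatrix(
            features=pd.DataFrame(feats), samples=[f"s{i}" for i in range(n)],
            values=np.exp(2 + 0.5 * vals), state="tpm",
        )
        norm = pp.inverse_normal_transform(expr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, sweep = pp.select_latent_factor_count(
                norm, [0, 5], panel, None, None,
                genes_per_decile=4, cis_window=400,
            )
        counts = dict(zip(sweep["n_factors"], sweep["n_eqtls"]))
        assert counts[5] > counts[0]
        assert best == 5

    def test_sweep_is_deterministic(self, mapped_small_study):
        args = (
            mapped_small_study["norm"], [0, 2], mapped_small_study["panel"],
            None, mapped_small_study["kinship"],
        )
        b1, s1 = pp.select_latent_factor_count(*args, genes_per_decile=2, seed=5)
        b2, s2 = pp.select_latent_factor_count(*args, genes_per_decile=2, seed=5)
        assert b1 == b2 and s1.equals(s2)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_retained_counts_match_reference_on_random_fixtures(seed):
    """Gene-filter retention equals an independent per-row count on random
    matrices (property over seeds)."""
    rng = np.random.default_rng(seed)
    vals = rng.exponential(1.0, size=(12, 30))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = pp.filter_expressed_genes(_expr(vals))
    expected = sum((row >= 1).sum() >= 3 for row in vals)
    assert out.n_features == expected
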