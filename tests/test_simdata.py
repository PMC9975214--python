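"""The synthetic cohort generator: LD structure, planted relatedness,
expression generative model, GWAS summary statistics, determinism and
file round-trips."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardioqtl.ld import ld_from_haplotypes
from cardioqtl.preprocess import compute_kinship
from cardioqtl.simdata import (
    SimulationConfig,
    simulate_cohort,
    simulate_haplotypes,
)
from cardioqtl.simdata.io import read_vcf, write_vcf


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="fractions"):
            SimulationConfig(fraction_null=0.9)

    def test_maf_range_bounds(self):
        with pytest.raises(ValueError, match="maf_range"):
            SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError, match="maf_range"):
            SimulationConfig(maf_range=(0.1, 0.6))

    def test_too_few_variants_rejected(self):
        with pytest.raises(ValueError, match="n_variants_per_locus"):
            SimulationConfig(n_variants_per_locus=1)

    def test_small_gwas_cohort_rejected(self):
        with pytest.raises(ValueError, match="gwas_n"):
            SimulationConfig(gwas_n=10)


class TestLDStructure:
    def test_independent_variants_have_no_ld(self):
        rng = np.random.default_rng(0)
        freqs = rng.uniform(0.1, 0.5, 1001)
        haps = simulate_haplotypes(1000, freqs, ld_rho=0.0, rng=rng)
        r2 = [
            ld_from_haplotypes(haps[:, j], haps[:, j + 1])[0] for j in range(1000)
        ]
        # mean adjacent r2 of independent sites is O(1/n)
        assert np.mean(r2) < 3 / np.sqrt(1000)

    def test_ld_decays_with_distance(self):
        rng = np.random.default_rng(1)
        freqs = rng.uniform(0.1, 0.5, 60)
        haps = simulate_haplotypes(500, freqs, ld_rho=0.95, rng=rng)
        adj = np.array([ld_from_haplotypes(haps[:, j], haps[:, j + 1])[0] for j in range(59)])
        lag10 = np.array([ld_from_haplotypes(haps[:, j], haps[:, j + 10])[0] for j in range(50)])
        res = stats.mannwhitneyu(adj, lag10, alternative="greater")
        assert res.pvalue < 0.01

    def test_realized_maf_tracks_target_range(self):
        rng = np.random.default_rng(2)
        freqs = rng.uniform(0.2, 0.4, 200)
        haps = simulate_haplotypes(2000, freqs, ld_rho=0.9, rng=rng)
        realized = haps.mean(axis=0)
        assert np.all(np.abs(realized - freqs) < 0.05)


class TestRelatedness:
    def test_planted_relatives_have_pedigree_kinship(self, small_study):
        kin = compute_kinship(small_study.panel)
        rel = small_study.relationship
        n = rel.shape[0]
        iu = np.triu_indices(n, 1)
        sib = rel[iu] == 0.5
        unrel = rel[iu] == 0.0
        assert 0.20 <= kin[iu][sib].mean() <= 0.30
        assert -0.05 <= kin[iu][unrel].mean() <= 0.05

    def test_repeated_donor_samples_match_diagonal(self, small_study):
        kin = compute_kinship(small_study.panel)
        rel = small_study.relationship
        iu = np.triu_indices(rel.shape[0], 1)
        dup = rel[iu] == 1.0
        if dup.any():
            assert abs(kin[iu][dup].mean() - np.diag(kin).mean()) < 0.02


class TestExpressionModel:
    def test_null_gene_pvalues_are_uniform(self):
        """With no planted effect the per-variant association p-values must
        be uniform (null calibration of the generative model)."""
        rng = np.random.default_rng(3)
        n = 300
        ps = []
        for _ in range(500):
            x = rng.binomial(2, 0.3, n) / 2.0
            y = rng.standard_normal(n)
            r = stats.linregress(x, y)
            ps.append(r.pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_specific_eqtl_only_acts_in_context(self, small_study):
        """A planted context-specific effect shows the planted slope in the
        context subsample and a null slope outside it."""
        truth = small_study.truth
        spec = truth[
            (truth["label"] == "specific") & (truth["context_kind"] != "cell_type")
        ]
        if spec.empty:
            pytest.skip("no binary-context specific gene in this draw")
        checked = 0
        ctx_by_name = {c.name: c for c in small_study.contexts}
        for _, row in spec.iterrows():
            z = ctx_by_name[row["context"]].values.astype(bool)
            if z.sum() < 30:
                continue
            i = truth.index[truth["gene_id"] == row["gene_id"]][0]
            y = small_study.latent_genes[i]
            j = small_study.panel.variants.index[
                small_study.panel.variants["id"] == row["causal_variant"]
            ][0]
            x = small_study.panel.dosages[:, j]
            x = (x - x.mean()) / x.std()
            r_in = stats.linregress(x[z], y[z])
            r_out = stats.linregress(x[~z], y[~z])
            assert abs(r_in.slope - row["effect"]) < 2.5 * r_in.stderr
            assert abs(r_out.slope) < 3 * r_out.stderr
            checked += 1
        if checked == 0:
            pytest.skip("no sufficiently large context subset")

    def test_opposite_usage_effects_cancel_at_gene_level(self, small_study):
        truth = small_study.truth
        with_usage = truth[
            (truth["usage_qtl_variant"] != "")
            & (truth["usage_qtl_variant"] != truth["causal_variant"])
            & (~truth["low_expression"])
        ]
        assert not with_usage.empty
        row = with_usage.iloc[0]
        i = truth.index[truth["gene_id"] == row["gene_id"]][0]
        j = small_study.panel.variants.index[
            small_study.panel.variants["id"] == row["usage_qtl_variant"]
        ][0]
        x = small_study.panel.dosages[:, j]
        x = (x - x.mean()) / x.std()
        # gene-level association with the usage variant is null
        y_gene = small_study.latent_genes[i]
        r_gene = stats.linregress(x, y_gene)
        assert abs(r_gene.slope) < 3 * r_gene.stderr
        # usage of the two switched isoforms is strongly associated
        iso = small_study.expr_isoforms
        k1 = iso.features.index[iso.features["id"] == f"{row['gene_id']}.1"][0]
        k2 = iso.features.index[iso.features["id"] == f"{row['gene_id']}.2"][0]
        r1 = stats.linregress(x, iso.usage[k1])
        r2 = stats.linregress(x, iso.usage[k2])
        assert r1.pvalue < 1e-6 and r2.pvalue < 1e-6
        assert np.sign(r1.slope) == -np.sign(r2.slope)

    def test_isoform_usage_sums_to_one(self, small_study):
        iso = small_study.expr_isoforms
        sums = pd.DataFrame(iso.usage).groupby(iso.features["gene_id"].to_numpy()).sum()
        assert np.allclose(sums.to_numpy(), 1.0, atol=1e-9)


class TestGWASSimulation:
    def test_h3_causal_variant_in_low_ld(self, small_study):
        truth = small_study.truth
        panel = small_study.panel
        idx = {v: i for i, v in enumerate(panel.variants["id"])}
        h3 = truth[truth["gwas_relation"] == "H3"]
        assert not h3.empty
        for _, row in h3.iterrows():
            r2, _ = ld_from_haplotypes(
                panel.haplotypes[:, idx[row["causal_variant"]]],
                panel.haplotypes[:, idx[row["gwas_causal_variant"]]],
            )
            assert r2 < 0.2

    def test_h4_gwas_signal_is_genome_wide_significant(self, small_study):
        truth = small_study.truth
        for _, row in truth[truth["gwas_relation"] == "H4"].iterrows():
            tab = small_study.gwas[row["gwas_trait"]].table
            sub = tab[tab["id"] == row["gwas_causal_variant"]]
            assert (sub["pval"] < 5e-8).all()

    def test_null_locus_rarely_significant(self):
        cfg = SimulationConfig(
            n_samples=100, n_individuals=100, n_genes=6, n_variants_per_locus=40,
            n_multigenic_groups=0, n_antisense_pairs=0, fraction_specific=0.0,
            fraction_associated=0.0, fraction_shared=0.0, fraction_null=1.0,
            gwas_n=2000, gwas_null_loci=6, seed=11,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            study = simulate_cohort(cfg)
        for gw in study.gwas.values():
            assert (gw.table["pval"] > 5e-8).all()


class TestTruthCompleteness:
    def test_planted_effects_recoverable_by_subset_ols(self, small_study):
        """Every planted effect is recoverable by a direct per-subset OLS
        oracle on the model-scale expression (power >= 0.9 at defaults)."""
        truth = small_study.truth
        panel = small_study.panel
        ctx_by_name = {c.name: c for c in small_study.contexts}
        idx = {v: i for i, v in enumerate(panel.variants["id"])}
        planted = truth[(truth["label"] != "null") & (~truth["low_expression"])]
        hits = total = 0
        for i, row in planted.iterrows():
            x = panel.dosages[:, idx[row["causal_variant"]]]
            if x.std() == 0:
                continue
            x = (x - x.mean()) / x.std()
            y = small_study.latent_genes[i]
            if row["label"] == "shared":
                sel = np.ones(len(x), dtype=bool)
            else:
                z = ctx_by_name[row["context"]].values
                if row["context_kind"] == "cell_type":
                    sel = z >= np.quantile(z, 0.75)  # top quartile oracle
                else:
                    sel = z > 0.5
                if sel.sum() < 30:
                    continue
            r = stats.linregress(x[sel], y[sel])
            hits += int(r.pvalue < 0.05)
            total += 1
        assert total > 10
        assert hits / total >= 0.9

    def test_tsv_round_trips_bit_exactly(self, small_study, tmp_path):
        from cardioqtl.simdata.io import (
            read_expression_tsv,
            read_gwas_tsv,
            write_expression_tsv,
            write_gwas_tsv,
        )

        p1, p2 = tmp_path / "e1.tsv", tmp_path / "e2.tsv"
        write_expression_tsv(small_study.expr_genes, p1)
        back = read_expression_tsv(p1, small_study.expr_genes.features)
        write_expression_tsv(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

        g1, g2 = tmp_path / "g1.tsv", tmp_path / "g2.tsv"
        trait = next(iter(small_study.gwas))
        write_gwas_tsv(small_study.gwas[trait], g1)
        write_gwas_tsv(read_gwas_tsv(g1, trait), g2)
        assert g1.read_bytes() == g2.read_bytes()


class TestDeterminism:
    def test_same_seed_same_study(self, small_config):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = simulate_cohort(small_config)
            b = simulate_cohort(small_config)
        assert np.array_equal(a.panel.dosages, b.panel.dosages)
        assert np.array_equal(a.expr_genes.values, b.expr_genes.values)
        assert a.truth.equals(b.truth)
        for t in a.gwas:
            assert a.gwas[t].table.equals(b.gwas[t].table)

    def test_vcf_round_trip_is_byte_exact(self, small_study, tmp_path):
        p1 = tmp_path / "a.vcf"
        p2 = tmp_path / "b.vcf"
        write_vcf(small_study.panel, p1)
        panel2 = read_vcf(p1)
        assert panel2.samples == small_study.panel.samples
        assert np.array_equal(
            panel2.dosages, small_study.panel.dosages, equal_nan=True
        )
        write_vcf(panel2, p2)
        assert p1.read_bytes() == p2.read_bytes()
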