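import warnings

import numpy as np
import pytest

from cardioqtl.simdata import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_samples=300,
        n_individuals=250,
        n_genes=40,
        n_variants_per_locus=80,
        n_multigenic_groups=3,
        n_antisense_pairs=3,
        related_pair_fraction=0.15,
        gwas_n=8000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def mapped_small_study(small_study):
    """Preprocessed pipeline state plus mapped eQTL signals for the small
    cohort, shared across test modules."""
    from cardioqtl import preprocess as pp
    from cardioqtl.eqtl import map_eqtls

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr = pp.filter_expressed_genes(small_study.expr_genes)
        norm = pp.inverse_normal_transform(expr)
        panel = pp.filter_variants(small_study.panel, expr)
        kin = pp.compute_kinship(panel)
        pcs = pp.compute_genotype_pcs(panel, k=5)
        lat = pp.expression_latent_factors(norm.values, 5)
        cov = np.column_stack([small_study.covariate_matrix, pcs, lat])
        signals, features = map_eqtls(norm, panel, cov, kin)
    return {
        "expr": expr,
        "norm": norm,
        "panel": panel,
        "kinship": kin,
        "covariates": cov,
        "signals": signals,
        "features": features,
    }
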