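"""Apply the study's expression and variant filters, inverse-normal
normalization, kinship / genotype-PC computation, and the latent-factor-
count selection sweep; write the preprocessing report."""

import numpy as np
import pandas as pd
from common import RESULTS, get_pipeline_state, get_study, step_timer

from cardioqtl import preprocess as pp


def main():
    study = get_study()
    with step_timer("preprocess"):
        state = get_pipeline_state(study)
    outdir = RESULTS / "preprocess"
    outdir.mkdir(parents=True, exist_ok=True)

    print(f"expressed genes: {state['expr'].n_features} / {study.expr_genes.n_features} "
          f"(TPM >= 1 in >= 10% of samples)")
    print(f"isoforms kept: {state['iso'].n_features} / {study.expr_isoforms.n_features} "
          f"(TPM >= 1 and usage > 10% in >= 10%, >= 2 per gene)")
    print(f"variants kept: {state['panel'].n_variants} / {study.panel.n_variants} "
          f"(MAF > 1%, HWE p > 1e-6, call rate >= 99%, within 500 kb of an expressed gene)")
    kin = state["kinship"]
    iu = np.triu_indices_from(kin, 1)
    rel = study.relationship[iu]
    print(f"kinship: mean diag {np.diag(kin).mean():.3f}; "
          f"planted first-degree pairs {kin[iu][rel == 0.5].mean():.3f}; "
          f"unrelated {kin[iu][rel == 0.0].mean():.4f}")

    with step_timer("latent-factor sweep"):
        best, sweep = pp.select_latent_factor_count(
            state["norm"], [0, 2, 5, 10, 15], state["panel"],
            np.column_stack([study.covariate_matrix,
                             pp.compute_genotype_pcs(state["panel"], k=5)]),
            state["kinship"], genes_per_decile=5, seed=1,
        )
    sweep.to_csv(outdir / "latent_factor_sweep.tsv", sep="\t", index=False)
    print(f"latent-factor sweep: {dict(zip(sweep['n_factors'], sweep['n_eqtls']))}; "
          f"selected {best} factors (ties break toward fewer)")

    state["panel"].variants.to_csv(outdir / "variants_filtered.tsv", sep="\t",
                                   index=False, float_format="%.6g")
    pd.DataFrame(state["kinship"]).to_csv(outdir / "kinship.tsv", sep="\t",
                                          index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
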