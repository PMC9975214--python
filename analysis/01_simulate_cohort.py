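"""Generate the synthetic spatiotemporal cardiac cohort and write every
study artifact (VCF genotypes, TPM/usage matrices, metadata, GWAS summary
statistics, planted-truth table) under results/study/."""

from common import RESULTS, STUDY_CONFIG, get_study, step_timer

from cardioqtl.simdata.io import write_study


def main():
    with step_timer("simulate cohort"):
        study = get_study()
    outdir = RESULTS / "study"
    paths = write_study(study, outdir)

    truth = study.truth
    print(f"cohort: {STUDY_CONFIG.n_samples} samples from "
          f"{STUDY_CONFIG.n_individuals} donors; "
          f"{study.panel.n_variants} variants in {STUDY_CONFIG.n_genes} loci")
    print(f"stage split: {study.samples['stage'].value_counts().to_dict()}")
    print(f"planted labels: {truth['label'].value_counts().to_dict()}")
    print(f"GWAS relations: {truth['gwas_relation'].value_counts().to_dict()}")
    print(f"multigenic groups: {truth.loc[truth['multigenic_group'] >= 0, 'multigenic_group'].nunique()}, "
          f"antisense pairs: {(truth['antisense_partner'] != '').sum() // 2}")
    print(f"wrote {len(paths)} artifacts to {outdir}")


if __name__ == "__main__":
    main()
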