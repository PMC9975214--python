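"""On-disk formats for the synthetic study: VCF genotypes, TSV expression /
metadata / GWAS / truth tables, YAML config. Writers are byte-deterministic
for a fixed study; the VCF reader round-trips the writer exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ..types import ExpressionMatrix, GenotypePanel, GWASSummaryStats
from .config import SimulationConfig

FLOAT_FORMAT = "%.6g"


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Diploid biallelic SNVs with GT calls derived from the {0,0.5,1} dosages."""
    path = Path(path)
    gt_map = {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(panel.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for j, v in panel.variants.iterrows():
            calls = [
                gt_map.get(float(d), "./.") if not np.isnan(d) else "./."
                for d in panel.dosages[:, j]
            ]
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a VCF back into a panel (GT field -> {0, 0.5, 1} dosages)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta, rows = [], []
    for var in vcf:
        meta.append(
            {
                "id": var.ID,
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
            }
        )
        gts = var.genotypes
        row = np.empty(len(samples))
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            row[i] = np.nan if (a < 0 or b < 0) else (a + b) / 2.0
        rows.append(row)
    return GenotypePanel(
        variants=pd.DataFrame(meta),
        dosages=np.vstack(rows).T if rows else np.empty((len(samples), 0)),
        samples=samples,
    )


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, columns=expr.samples)
    df.insert(0, "feature_id", expr.features["id"].to_numpy())
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_expression_tsv(
    path: str | Path, features: pd.DataFrame, state: str = "tpm"
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    samples = [c for c in df.columns if c != "feature_id"]
    feat = features.set_index("id").loc[df["feature_id"]].reset_index()
    return ExpressionMatrix(
        features=feat, samples=samples,
        values=df[samples].to_numpy(dtype=float), state=state,
    )


def write_gwas_tsv(gwas: GWASSummaryStats, path: str | Path) -> None:
    gwas.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_gwas_tsv(path: str | Path, trait: str, n: int = 0) -> GWASSummaryStats:
    return GWASSummaryStats(trait=trait, table=pd.read_csv(path, sep="\t"), n=n)


def write_study(study, outdir: str | Path) -> dict[str, Path]:
    """Write the complete study; returns the path of every artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "genes": outdir / "expression_genes_tpm.tsv",
        "isoforms": outdir / "expression_isoforms_tpm.tsv",
        "usage": outdir / "isoform_usage.tsv",
        "features_genes": outdir / "features_genes.tsv",
        "features_isoforms": outdir / "features_isoforms.tsv",
        "samples": outdir / "samples.tsv",
        "covariates": outdir / "covariates.tsv",
        "cell_fractions": outdir / "cell_fractions.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    write_vcf(study.panel, paths["vcf"])
    write_expression_tsv(study.expr_genes, paths["genes"])
    write_expression_tsv(study.expr_isoforms, paths["isoforms"])
    usage = pd.DataFrame(study.expr_isoforms.usage, columns=study.expr_isoforms.samples)
    usage.insert(0, "feature_id", study.expr_isoforms.features["id"].to_numpy())
    usage.to_csv(paths["usage"], sep="\t", index=False, float_format=FLOAT_FORMAT)
    study.expr_genes.features.to_csv(paths["features_genes"], sep="\t", index=False)
    study.expr_isoforms.features.to_csv(paths["features_isoforms"], sep="\t", index=False)
    study.samples.to_csv(paths["samples"], sep="\t", index=False)
    study.covariates.to_csv(
        paths["covariates"], sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    study.cell_fractions.to_csv(
        paths["cell_fractions"], sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    study.truth.to_csv(paths["truth"], sep="\t", index=False, float_format=FLOAT_FORMAT)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(study.config.to_dict(), fh, sort_keys=True)
    for trait, gw in study.gwas.items():
        p = outdir / f"gwas_{trait}.tsv"
        paths[f"gwas_{trait}"] = p
        write_gwas_tsv(gw, p)
    return paths
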