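"""Assembly of the planted-truth table: which gene gets which causal
variant, effect size, context label, locus-sharing structure, and GWAS
relation. Every downstream analysis is scored against this table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..ld import ld_from_haplotypes
from ..types import GenotypePanel
from .config import SimulationConfig

GENE_SPAN = 10_000
GENE_OFFSET = 20_000


def _draw_label(rng: np.random.Generator, config: SimulationConfig) -> str:
    return str(rng.choice(
        ["specific", "associated", "shared", "null"],
        p=[
            config.fraction_specific,
            config.fraction_associated,
            config.fraction_shared,
            config.fraction_null,
        ],
    ))


def _draw_context(rng: np.random.Generator, config: SimulationConfig) -> tuple[str, str]:
    choices = config.binary_contexts + [(c, "cell_type") for c in config.cell_types]
    name, kind = choices[rng.integers(len(choices))]
    return name, kind


def _low_ld_variant(
    panel: GenotypePanel, locus_slice: slice, anchor: int, max_r2: float,
    rng: np.random.Generator,
) -> int:
    """A variant index (absolute) in the locus with r^2 < max_r2 to the anchor."""
    idx = np.arange(locus_slice.start, locus_slice.stop)
    order = rng.permutation(idx)
    h_anchor = panel.haplotypes[:, anchor]
    for j in order:
        if j == anchor:
            continue
        r2, _ = ld_from_haplotypes(h_anchor, panel.haplotypes[:, j])
        if np.isfinite(r2) and r2 < max_r2:
            return int(j)
    raise RuntimeError(
        "no variant in sufficiently low LD with the anchor; "
        "lower ld_rho or enlarge the locus"
    )


def build_truth(
    config: SimulationConfig,
    panel: GenotypePanel,
    locus_slices: list[slice],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One row per gene: locus assignment, coordinates, planted label,
    causal variant, effect, sharing structure, GWAS relation, isoform plan."""
    n = config.n_genes
    group_sizes = []
    remaining = n - 2 * config.n_antisense_pairs
    for _ in range(config.n_multigenic_groups):
        size = int(rng.integers(config.multigenic_group_size[0],
                                config.multigenic_group_size[1] + 1))
        if remaining - size < 0:
            break
        group_sizes.append(size)
        remaining -= size
    n_single = remaining
    if n_single < 0:
        raise ValueError("n_genes too small for the requested locus-sharing structure")

    rows = []
    gene_idx = 0
    locus = 0

    def locus_center(lslice: slice) -> int:
        return (lslice.start + lslice.stop) // 2

    def gene_coords(lslice: slice, k: int) -> tuple[str, int, int]:
        sub = panel.variants.iloc[lslice]
        chrom = sub["chrom"].iloc[0]
        mid = sub["pos"].iloc[len(sub) // 2]
        start = int(mid + k * GENE_OFFSET)
        return chrom, start, start + GENE_SPAN

    def causal_at(lslice: slice, jitter: int = 5) -> int:
        c = locus_center(lslice)
        j = int(c + rng.integers(-jitter, jitter + 1))
        return int(np.clip(j, lslice.start, lslice.stop - 1))

    def new_row(gene_id, symbol, lslice, k, label, context, kind, causal, effect,
                group_id=-1, partner=""):
        chrom, start, end = gene_coords(lslice, k)
        return {
            "gene_id": gene_id,
            "symbol": symbol,
            "locus": locus,
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": "+" if (gene_idx % 2 == 0) else "-",
            "label": label,
            "context": context,
            "context_kind": kind,
            "causal_variant": causal,
            "effect": effect,
            "multigenic_group": group_id,
            "antisense_partner": partner,
            "gwas_relation": "none",
            "gwas_trait": "",
            "gwas_causal_variant": "",
            "n_isoforms": int(
                rng.integers(config.isoforms_per_gene[0], config.isoforms_per_gene[1] + 1)
            ),
            "usage_qtl_variant": "",
            "usage_effect": 0.0,
            "low_expression": False,
        }

    # multigenic groups: one locus, one causal variant, one label for the group
    for gid, size in enumerate(group_sizes):
        lslice = locus_slices[locus]
        causal = causal_at(lslice)
        label = _draw_label(rng, config)
        if label == "null":
            label = "shared"  # groups exist to carry a signal
        context, kind = ("", "")
        if label in ("specific", "associated"):
            context, kind = _draw_context(rng, config)
        effect = float(rng.choice(config.effect_grid)) * float(rng.choice([-1, 1]))
        for k in range(size):
            gene_id = f"G{gene_idx:04d}"
            rows.append(
                new_row(gene_id, gene_id, lslice, k, label, context, kind,
                        panel.variants["id"].iloc[causal], effect, group_id=gid)
            )
            gene_idx += 1
        locus += 1

    # antisense pairs: GENE + GENE-AS1 symbols in one locus
    for p in range(config.n_antisense_pairs):
        lslice = locus_slices[locus]
        shared = rng.random() < config.antisense_shared_fraction
        causal = causal_at(lslice)
        causal_id = panel.variants["id"].iloc[causal]
        effect = float(rng.choice(config.effect_grid)) * float(rng.choice([-1, 1]))
        id_a, id_b = f"G{gene_idx:04d}", f"G{gene_idx + 1:04d}"
        sym = f"ASG{p}"
        for k, (gid_, sym_) in enumerate([(id_a, sym), (id_b, f"{sym}-AS1")]):
            if shared or k == 0:
                cv, eff = causal_id, effect
            else:
                alt = _low_ld_variant(panel, lslice, causal, config.h3_max_r2, rng)
                cv = panel.variants["id"].iloc[alt]
                eff = float(rng.choice(config.effect_grid)) * float(rng.choice([-1, 1]))
            row = new_row(gid_, sym_, lslice, k, "shared", "", "", cv, eff,
                          partner=(id_b if k == 0 else id_a))
            rows.append(row)
            gene_idx += 1
        locus += 1

    # singleton genes
    for _ in range(n_single):
        lslice = locus_slices[locus]
        gene_id = f"G{gene_idx:04d}"
        label = _draw_label(rng, config)
        context, kind = ("", "")
        causal_id, effect = "", 0.0
        if label != "null":
            causal_id = panel.variants["id"].iloc[causal_at(lslice)]
            effect = float(rng.choice(config.effect_grid)) * float(rng.choice([-1, 1]))
            if label in ("specific", "associated"):
                context, kind = _draw_context(rng, config)
        row = new_row(gene_id, gene_id, lslice, 0, label, context, kind, causal_id, effect)
        if label == "null" and rng.random() < config.low_expression_fraction / max(
            config.fraction_null, 1e-9
        ):
            row["low_expression"] = True
        rows.append(row)
        gene_idx += 1
        locus += 1

    truth = pd.DataFrame(rows)

    # usage-eQTLs: an independent (low-LD) variant drives isoform switching
    id_to_idx = {v: i for i, v in enumerate(panel.variants["id"])}
    for i in truth.index:
        if truth.at[i, "n_isoforms"] < 2 or truth.at[i, "low_expression"]:
            continue
        if rng.random() >= config.usage_qtl_fraction:
            continue
        # a usage-eQTL either shares the gene's causal variant (so the
        # eIsoform and eGene signals colocalize) or sits at an independent
        # low-LD variant (a different signal than the associated eGene)
        independent = rng.random() < config.usage_independent_fraction
        if not independent and truth.at[i, "causal_variant"]:
            truth.at[i, "usage_qtl_variant"] = truth.at[i, "causal_variant"]
            truth.at[i, "usage_effect"] = config.usage_effect * float(rng.choice([-1, 1]))
            continue
        lslice = locus_slices[truth.at[i, "locus"]]
        anchor = (
            id_to_idx[truth.at[i, "causal_variant"]]
            if truth.at[i, "causal_variant"]
            else (lslice.start + lslice.stop) // 2
        )
        try:
            uv = _low_ld_variant(panel, lslice, anchor, config.h3_max_r2, rng)
        except RuntimeError:
            continue
        truth.at[i, "usage_qtl_variant"] = panel.variants["id"].iloc[uv]
        truth.at[i, "usage_effect"] = config.usage_effect * float(rng.choice([-1, 1]))

    # GWAS relations among genes carrying an eQTL; at most one relation per
    # locus so each trait's summary table has one row per variant
    eligible = truth.index[(truth["label"] != "null") & (~truth["low_expression"])]
    n_h4 = int(round(config.gwas_h4_fraction * len(eligible)))
    n_h3 = int(round(config.gwas_h3_fraction * len(eligible)))
    pick = rng.permutation(eligible.to_numpy())
    used_loci: set[int] = set()
    n_done_h4 = n_done = 0
    for i in pick:
        if n_done >= n_h4 + n_h3:
            break
        loc = truth.at[i, "locus"]
        if loc in used_loci:
            continue
        used_loci.add(loc)
        trait = config.gwas_traits[n_done % len(config.gwas_traits)]
        if n_done_h4 < n_h4:
            truth.at[i, "gwas_relation"] = "H4"
            truth.at[i, "gwas_causal_variant"] = truth.at[i, "causal_variant"]
            n_done_h4 += 1
        else:
            lslice = locus_slices[loc]
            anchor = id_to_idx[truth.at[i, "causal_variant"]]
            alt = _low_ld_variant(panel, lslice, anchor, config.h3_max_r2, rng)
            truth.at[i, "gwas_relation"] = "H3"
            truth.at[i, "gwas_causal_variant"] = panel.variants["id"].iloc[alt]
        truth.at[i, "gwas_trait"] = trait
        n_done += 1
    return truth
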