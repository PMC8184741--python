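"""CLPP colocalization of eQTL and trait posteriors, and gene prioritization.

The colocalization posterior probability (CLPP) for a gene in a region is
the maximum, over tissues and over the variants of the unresolved trait
credible set, of (eQTL PIP x trait PIP).  A gene is prioritized when its
CLPP exceeds 0.1 and is the strict maximum among the genes of its region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLPP_THRESHOLD = 0.1


@dataclass
class ColocRecord:
    gene_id: str
    trait: str
    region_id: str
    clpp: float
    argmax_variant: str
    argmax_tissue: str
    prioritized: bool = False


def clpp(
    eqtl_pips: dict[str, dict[str, float]] | dict[str, float],
    trait_pips: dict[str, float],
    credible_variants: set[str] | list[str] | None = None,
) -> tuple[float, str, str]:
    """Max over tissues and credible variants of eQTL PIP x trait PIP.

    ``eqtl_pips`` is either ``{tissue: {variant: pip}}`` or a flat
    ``{variant: pip}`` (treated as one unnamed tissue).  Ties break on
    ascending (variant id, tissue).  Returns (clpp, argmax variant, argmax
    tissue).
    """
    if eqtl_pips and not isinstance(next(iter(eqtl_pips.values())), dict):
        eqtl_pips = {"": eqtl_pips}  # single-tissue shorthand
    candidates = set(trait_pips)
    if credible_variants is not None:
        candidates &= set(credible_variants)
    best: tuple[float, str, str] | None = None
    found = False
    for tissue in sorted(eqtl_pips):
        tissue_pips = eqtl_pips[tissue]
        for v in sorted(candidates & set(tissue_pips)):
            found = True
            prod = float(tissue_pips[v]) * float(trait_pips[v])
            if best is None or prod > best[0]:
                best = (prod, v, tissue)
    if not found:
        raise ValueError("no overlap between eQTL and trait variants")
    return best


def prioritize_genes(
    region_clpp: dict[str, dict[str, float]],
    threshold: float = CLPP_THRESHOLD,
) -> dict[str, str | None]:
    """Per region, the strict-maximum gene with CLPP above the threshold.

    ``region_clpp`` maps region id -> {gene id: clpp}.  A tie at the
    maximum prioritizes no gene.
    """
    out: dict[str, str | None] = {}
    for region, genes in region_clpp.items():
        if not genes:
            raise ValueError(f"region {region!r} has no genes")
        top = max(genes.values())
        winners = [g for g, c in genes.items() if c == top]
        out[region] = winners[0] if (top > threshold and len(winners) == 1) else None
    return out


def precision_recall(
    prioritized: dict[str, str | None],
    correct_gene: dict[str, str],
    evaluation_genes: set[str] | list[str],
) -> dict:
    """Precision / recall of gene prioritization against the evaluation set.

    Precision = correctly prioritized / prioritized (NaN when nothing is
    prioritized); recall = correctly prioritized / #evaluation genes.
    """
    evaluation_genes = set(evaluation_genes)
    if not evaluation_genes:
        raise ValueError("evaluation gene set is empty")
    picked = {r: g for r, g in prioritized.items() if g is not None}
    n_prioritized = len(picked)
    n_correct = sum(1 for r, g in picked.items() if correct_gene.get(r) == g)
    precision = n_correct / n_prioritized if n_prioritized else float("nan")
    recall = n_correct / len(evaluation_genes)
    return {"precision": precision, "recall": recall,
            "n_prioritized": n_prioritized, "n_correct": n_correct,
            "n_evaluation": len(evaluation_genes)}


def unresolved_regions(
    trait_table: pd.DataFrame,
    half_width: int = 500_000,
    coding_pip_threshold: float = 0.1,
    evaluation_pip_threshold: float = 0.5,
) -> pd.DataFrame:
    """Regions around unresolved trait credible sets, with evaluation genes.

    ``trait_table`` needs columns: variant_id, chrom, pos, trait_pip,
    cs_id, is_coding, gene_id (gene for coding variants).  A credible set is
    unresolved when none of its coding variants has trait PIP above
    ``coding_pip_threshold``; the region is the set's center +/-
    ``half_width`` and is kept only if it contains an evaluation gene (a
    coding variant with trait PIP > ``evaluation_pip_threshold``).
    """
    rows = []
    for cs_id, grp in trait_table.groupby("cs_id"):
        coding = grp[grp["is_coding"].astype(bool)]
        if (coding["trait_pip"] > coding_pip_threshold).any():
            continue  # resolved by a coding variant
        center = int(grp["pos"].median())
        chrom = grp["chrom"].iloc[0]
        lo, hi = center - half_width, center + half_width
        window = trait_table[(trait_table["chrom"] == chrom)
                             & trait_table["pos"].between(lo, hi)]
        eval_genes = sorted(set(
            window.loc[window["is_coding"].astype(bool)
                       & (window["trait_pip"] > evaluation_pip_threshold),
                       "gene_id"].dropna()))
        if not eval_genes:
            continue
        rows.append({"region_id": f"region_{cs_id}", "chrom": chrom,
                     "start": lo, "end": hi, "cs_id": cs_id,
                     "evaluation_genes": ",".join(eval_genes)})
    return pd.DataFrame(rows)
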