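"""Tissue-specific putative causal eQTLs and TF-feature enrichment tests.

A variant-gene pair is a tissue-specific putative causal eQTL for tissue T
when its PIP exceeds 0.9 in T and is below 0.1 — or missing — in every
other tissue.  A transcription factor is specific to tissue T when its TPM
in T is the unique maximum and exceeds the across-tissue mean by more than
two (sample) standard deviations; control tissues are those with TPM below
a tenth of T's, and calls without any control tissue are dropped.
Enrichment of a TF-linked feature is tested by a two-sided Welch t test
comparing its mean score in the tissue-specific eQTLs of the matched tissue
against those of the control tissues, at a Bonferroni-corrected level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

PIP_HI = 0.9
PIP_LO = 0.1


def classify_tissue_specific(
    pips: dict[str, float | None],
    hi: float = PIP_HI,
    lo: float = PIP_LO,
) -> str | None:
    """The single tissue with PIP > hi while all others are < lo or missing."""
    present = {t: p for t, p in pips.items() if p is not None and not np.isnan(p)}
    if len(pips) < 2:
        raise ValueError("need at least 2 tissues")
    winners = [t for t, p in present.items() if p > hi]
    if len(winners) != 1:
        return None
    t_star = winners[0]
    for t, p in present.items():
        if t != t_star and p >= lo:
            return None
    return t_star


@dataclass
class TfTissueCall:
    tf_name: str
    specific_tissue: str | None
    control_tissues: list[str]


def tf_tissue_specificity(
    tpm_row: dict[str, float],
    tf_name: str = "",
    control_ratio: float = 10.0,
) -> TfTissueCall:
    """Call a TF tissue-specific from its TPM profile across tissues.

    The specific tissue must be the unique maximum and exceed
    mean + 2 * sample sd (the mean and sd include the candidate tissue).
    Controls are the tissues expressed below max/``control_ratio``; a call
    with no control tissue is dropped (specific_tissue = None).
    """
    tissues = list(tpm_row)
    if len(tissues) < 3:
        raise ValueError("need at least 3 tissues")
    values = np.array([tpm_row[t] for t in tissues], dtype=float)
    if np.any(values < 0):
        raise ValueError("negative TPM")
    top = values.max()
    winners = np.flatnonzero(values == top)
    if winners.size != 1:
        return TfTissueCall(tf_name, None, [])
    t_star = tissues[int(winners[0])]
    if top <= values.mean() + 2.0 * values.std(ddof=1):
        return TfTissueCall(tf_name, None, [])
    controls = [t for t, v in zip(tissues, values) if v < top / control_ratio]
    if not controls:
        return TfTissueCall(tf_name, None, [])
    return TfTissueCall(tf_name, t_star, controls)


def tf_enrichment_test(
    specific_scores: np.ndarray,
    control_scores: np.ndarray,
    n_features_tested: int = 42,
    alpha: float = 0.05,
) -> dict:
    """Welch t test of feature-score means, Bonferroni over tested features."""
    specific_scores = np.asarray(specific_scores, dtype=float)
    control_scores = np.asarray(control_scores, dtype=float)
    if specific_scores.size < 2 or control_scores.size < 2:
        raise ValueError("need at least 2 eQTLs per group")
    if np.var(specific_scores) == 0 and np.var(control_scores) == 0:
        if specific_scores.mean() == control_scores.mean():
            return {"mean_difference": 0.0, "t": float("nan"),
                    "p": float("nan"), "significant": False}
        raise ValueError("degenerate variance in both groups")
    t, p = stats.ttest_ind(specific_scores, control_scores, equal_var=False)
    threshold = alpha / n_features_tested
    return {"mean_difference": float(specific_scores.mean() - control_scores.mean()),
            "t": float(t), "p": float(p), "significant": bool(p < threshold)}


def nearby_pairs(positions_a: np.ndarray, positions_b: np.ndarray,
                 max_distance: int = 10_000) -> list[tuple[int, int]]:
    """Index pairs (i, j) with |positions_a[i] - positions_b[j]| <= max_distance.

    Helper for finding tissue-specific eQTL pairs on the same gene in two
    tissues within a short genomic distance; no statistics attached.
    """
    a = np.asarray(positions_a)
    b = np.asarray(positions_b)
    out = []
    for i, pa in enumerate(a):
        for j, pb in enumerate(b):
            if abs(int(pa) - int(pb)) <= max_distance:
                out.append((i, j))
    return out
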