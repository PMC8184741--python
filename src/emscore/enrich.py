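"""Enrichment statistics, percentile binning, downsampling, score evaluation.

Enrichment of a set (e.g. putative causal pairs) in a score bin is the
probability of set membership given bin membership divided by the marginal
probability of set membership.  The standard error treats the denominator
as fixed (its sampling error is negligible at catalog scale) and propagates
the binomial error of the numerator proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

DEFAULT_DOWNSAMPLE_TOTAL = 100_000
# decile edges with a finer top bin at the 99th percentile
DEFAULT_PERCENTILE_EDGES = (10, 20, 30, 40, 50, 60, 70, 80, 90, 99)


@dataclass
class EnrichmentResult:
    bin_label: str
    n_bin: int
    n_set_in_bin: int
    n_total: int
    n_set: int
    enrichment: float
    se: float


def enrichment(set_flags: np.ndarray, bin_flags: np.ndarray,
               bin_label: str = "bin") -> EnrichmentResult:
    """(P[in set | in bin]) / (P[in set]), with binomial SE on the numerator."""
    set_flags = np.asarray(set_flags, dtype=bool)
    bin_flags = np.asarray(bin_flags, dtype=bool)
    n_total = set_flags.size
    n_bin = int(bin_flags.sum())
    n_set = int(set_flags.sum())
    if n_bin == 0:
        raise ValueError("empty bin: enrichment undefined")
    if n_set == 0:
        raise ValueError("empty set: enrichment undefined")
    n_set_in_bin = int((set_flags & bin_flags).sum())
    p_num = n_set_in_bin / n_bin
    p_den = n_set / n_total
    se_num = np.sqrt(p_num * (1.0 - p_num) / n_bin)
    return EnrichmentResult(bin_label, n_bin, n_set_in_bin, n_total, n_set,
                            p_num / p_den, se_num / p_den)


def percentile_bins(scores: np.ndarray,
                    edges: tuple[float, ...] = DEFAULT_PERCENTILE_EDGES) -> np.ndarray:
    """Assign right-closed percentile bins; tied scores share a bin.

    Returns integer bin indices 0..len(edges); bin k collects scores in
    (q_{k-1}, q_k], with the lowest bin closed below.
    """
    scores = np.asarray(scores, dtype=float)
    edges = tuple(edges)
    if any(not 0 < e < 100 for e in edges):
        raise ValueError("percentile edges must lie strictly inside (0, 100)")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("percentile edges must be strictly increasing")
    if len(edges) >= 1 and np.unique(scores).size == 1:
        raise ValueError("constant scores cannot be split into multiple bins")
    cuts = np.percentile(scores, edges)
    return np.searchsorted(cuts, scores, side="left").astype(int)


def downsample_keep_set(
    n_rows: int,
    set_flags: np.ndarray,
    target_total: int = DEFAULT_DOWNSAMPLE_TOTAL,
    seed: int = 0,
) -> np.ndarray:
    """Row indices keeping every set row plus random non-set rows to target.

    If the input already has at most ``target_total`` rows it is returned
    whole.  Deterministic per seed.
    """
    set_flags = np.asarray(set_flags, dtype=bool)
    n_set = int(set_flags.sum())
    if target_total < n_set:
        raise ValueError(f"target_total={target_total} below set size {n_set}")
    if n_rows <= target_total:
        return np.arange(n_rows)
    rng = np.random.default_rng(seed)
    set_idx = np.flatnonzero(set_flags)
    other = np.flatnonzero(~set_flags)
    fill = rng.choice(other, size=target_total - n_set, replace=False)
    return np.sort(np.concatenate([set_idx, fill]))


def score_eval(
    scores: np.ndarray,
    labels: np.ndarray,
    edges: tuple[float, ...] = DEFAULT_PERCENTILE_EDGES,
) -> dict:
    """AUROC, AUPRC and the per-percentile-bin enrichment table."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    bins = percentile_bins(scores, edges)
    rows = []
    for b in range(int(bins.max()) + 1):
        mask = bins == b
        if not mask.any():
            continue
        res = enrichment(labels, mask, bin_label=f"bin_{b}")
        rows.append(res.__dict__)
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "auprc": float(average_precision_score(labels, scores)),
        "enrichments": pd.DataFrame(rows),
    }
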