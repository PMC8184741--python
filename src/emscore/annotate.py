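"""Feature-matrix assembly for variant-gene pairs.

Variant positions are 1-based inclusive in all tables; BED intervals are
0-based half-open.  The conversion happens exactly once, inside
:func:`annotate_binary_overlap`.  Binary features record whether the variant
position falls in at least one interval of the feature (narrow-peak style
membership); continuous features are copied from per-variant or per-pair
score tables, with missing entries filled by a default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("emscore")

PAIR_KEY = ["chrom", "pos", "ref", "alt", "gene_id", "tissue"]


@dataclass(frozen=True)
class LabelRule:
    """Thresholds turning two fine-mapping PIPs into training labels."""

    pos_threshold: float = 0.9
    neg_threshold: float = 0.0001
    require_both_methods: bool = True

    def __post_init__(self) -> None:
        if not self.neg_threshold < self.pos_threshold:
            raise ValueError("neg_threshold must be below pos_threshold")


def distance_to_tss(variant_pos: int, tss_pos: int, strand: str = "+") -> int:
    """Signed distance from the TSS to the variant, in bp.

    Positive means downstream of the TSS in the direction of transcription:
    ``variant_pos - tss_pos`` on the plus strand, negated on the minus strand.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"unknown strand {strand!r}")
    d = int(variant_pos) - int(tss_pos)
    return -d if strand == "-" else d


def read_bed(path) -> list[tuple[str, int, int]]:
    """Parse a BED3+ file (0-based half-open); bad lines raise with their number."""
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer BED coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{ln}: end < start")
            intervals.append((parts[0], start, end))
    return intervals


def annotate_binary_overlap(
    pairs: pd.DataFrame,
    bed_features: dict[str, list[tuple[str, int, int]]],
) -> pd.DataFrame:
    """One {0,1} column per feature: 1 iff the variant lies in >=1 interval.

    The 1-based variant position ``pos`` is converted to 0-based (``pos - 1``)
    and tested against the half-open intervals.
    """
    out = {}
    for name, intervals in bed_features.items():
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if end > start:  # zero-length intervals cannot contain a point
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
        values = np.zeros(len(pairs), dtype=float)
        for i, (chrom, pos) in enumerate(zip(pairs["chrom"], pairs["pos"])):
            tree = trees.get(chrom)
            if tree is not None and tree.overlaps_point(int(pos) - 1):
                values[i] = 1.0
        out[name] = values
    return pd.DataFrame(out, index=pairs.index)


def annotate_continuous(
    pairs: pd.DataFrame,
    variant_scores: pd.DataFrame | None = None,
    pair_scores: pd.DataFrame | None = None,
    default: float = 0.0,
) -> pd.DataFrame:
    """Continuous score columns, keyed per variant or per (variant, gene).

    Per-pair values override per-variant values for the same column name.
    Missing entries are filled with ``default``; the fill count is logged.
    """
    frames = []
    if variant_scores is not None:
        cols = [c for c in variant_scores.columns if c != "variant_id"]
        merged = pairs[["variant_id"]].merge(variant_scores, on="variant_id", how="left")
        frames.append(merged[cols].set_axis(pairs.index))
    if pair_scores is not None:
        keys = ["variant_id", "gene_id"]
        cols = [c for c in pair_scores.columns if c not in keys]
        merged = pairs[keys].merge(pair_scores, on=keys, how="left")
        pair_frame = merged[cols].set_axis(pairs.index)
        if frames:
            shared = [c for c in cols if c in frames[0].columns]
            for c in shared:  # per-pair wins where present
                frames[0][c] = pair_frame[c].combine_first(frames[0][c])
            pair_frame = pair_frame.drop(columns=shared)
        frames.append(pair_frame)
    if not frames:
        return pd.DataFrame(index=pairs.index)
    out = pd.concat(frames, axis=1)
    for c in out.columns:
        if not np.issubdtype(out[c].dtype, np.number):
            raise ValueError(f"non-numeric value in continuous score column {c!r}")
    n_fill = int(out.isna().sum().sum())
    if n_fill:
        logger.warning("filled %d missing continuous feature values with %s", n_fill, default)
    return out.fillna(default)


def assemble_features(
    pairs: pd.DataFrame,
    bed_features: dict[str, list[tuple[str, int, int]]] | None = None,
    variant_scores: pd.DataFrame | None = None,
    pair_scores: pd.DataFrame | None = None,
    tss: pd.DataFrame | None = None,
    default: float = 0.0,
) -> pd.DataFrame:
    """Full model-ready feature matrix: distance + binary + continuous columns."""
    parts = []
    if "tss_distance" in pairs.columns:
        parts.append(pairs[["tss_distance"]].astype(float))
    elif tss is not None:
        merged = pairs.merge(tss, on=["gene_id", "chrom"], how="left")
        if merged["tss_pos"].isna().any():
            missing = pairs.loc[merged["tss_pos"].isna().to_numpy(), "gene_id"].unique()
            raise ValueError(f"genes missing from TSS table: {list(missing)[:5]}")
        dist = [
            distance_to_tss(p, t, s)
            for p, t, s in zip(merged["pos"], merged["tss_pos"], merged["strand"])
        ]
        parts.append(pd.DataFrame({"tss_distance": dist}, index=pairs.index, dtype=float))
    else:
        raise ValueError("need either a tss_distance column or a TSS table")
    if bed_features:
        parts.append(annotate_binary_overlap(pairs, bed_features))
    cont = annotate_continuous(pairs, variant_scores, pair_scores, default)
    if len(cont.columns):
        parts.append(cont)
    out = pd.concat(parts, axis=1)
    if out.columns.duplicated().any():
        dupes = out.columns[out.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature columns: {dupes}")
    return out


def feature_classes(columns) -> dict[str, str]:
    """Classify feature columns as distance / binary / continuous by name."""
    out = {}
    for c in columns:
        if c == "tss_distance":
            out[c] = "distance"
        elif c.startswith(("peak_", "bin_", "baseline_", "histone_")):
            out[c] = "binary"
        else:
            out[c] = "continuous"
    return out


def loco_split(pairs: pd.DataFrame, holdout_chrom: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-chromosome-out partition: (train rows, held-out rows)."""
    if holdout_chrom not in set(pairs["chrom"]):
        raise ValueError(f"holdout chromosome {holdout_chrom!r} absent from data")
    mask = pairs["chrom"] == holdout_chrom
    train, held = pairs[~mask], pairs[mask]
    if len(train) == 0:
        raise ValueError("empty training partition: all rows on the held-out chromosome")
    return train, held
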