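"""The expression modifier score: labels, classifier, calibration.

A random-forest classifier is trained to distinguish putative causal
variant-gene pairs (high posterior inclusion probability under both of two
fine-mapping methods) from confident negatives (very low PIP under both).
Its raw out-of-sample score is then calibrated to a probability by binning:
within each raw-score bin the fraction of positive labels is computed and
rescaled from the training prevalence to the genome-wide prevalence, giving
the expression modifier score (EMS) — the estimated probability that a pair
drawn at random from all candidate pairs is a causal eQTL.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .annotate import LabelRule, feature_classes

__all__ = [
    "LabelRule", "CalibrationTable", "EMSModel",
    "construct_labels", "select_features", "tune_and_train",
    "calibrate_to_ems", "score_pairs", "adjust_prior_ratio",
    "feature_importance_report", "train_ems_model",
]


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def construct_labels(pairs: pd.DataFrame, rule: LabelRule | None = None) -> pd.Series:
    """Label each pair positive / negative / unlabeled from its two PIPs.

    Positive iff both PIPs exceed ``rule.pos_threshold``; negative iff both
    fall below ``rule.neg_threshold``; everything else is unlabeled and is
    excluded from training.
    """
    rule = rule or LabelRule()
    for col in ("pip_a", "pip_b"):
        if col not in pairs.columns:
            raise ValueError(f"missing PIP column {col!r}")
        vals = pairs[col].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError(f"{col} contains values outside [0, 1]")
    a = pairs["pip_a"].to_numpy(dtype=float)
    b = pairs["pip_b"].to_numpy(dtype=float)
    if rule.require_both_methods:
        pos = np.minimum(a, b) > rule.pos_threshold
        neg = np.maximum(a, b) < rule.neg_threshold
    else:
        pos = np.maximum(a, b) > rule.pos_threshold
        neg = np.minimum(a, b) < rule.neg_threshold
    out = np.full(len(pairs), "unlabeled", dtype=object)
    out[pos] = "positive"
    out[neg] = "negative"
    return pd.Series(out, index=pairs.index, name="label")


def _balanced_subsample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of all positives plus an equal-size random negative sample."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present for training")
    if neg.size > pos.size:
        neg = rng.choice(neg, size=pos.size, replace=False)
    return np.sort(np.concatenate([pos, neg]))


# ---------------------------------------------------------------------------
# feature selection and training
# ---------------------------------------------------------------------------

def select_features(
    X: pd.DataFrame,
    y: np.ndarray,
    k: int = 152,
    seed: int = 0,
    n_estimators: int = 200,
) -> list[str]:
    """Top-``k`` feature names by mean-decrease-of-impurity importance.

    A preliminary forest is fit on the full matrix; features are ranked by
    MDI, ties broken lexicographically by name, and the top ``k`` returned in
    rank order.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds number of columns {X.shape[1]}")
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1)
    forest.fit(X.to_numpy(dtype=float), y)
    order = sorted(
        zip(-forest.feature_importances_, X.columns),
        key=lambda t: (t[0], t[1]),
    )
    return [name for _, name in order[:k]]


_BASE_PARAMS = dict(n_estimators=100, max_depth=None,
                    min_samples_leaf=1, max_features="sqrt")


def tune_and_train(
    X: pd.DataFrame,
    y: np.ndarray,
    search_budget: int = 10,
    seed: int = 0,
    val_fraction: float = 0.25,
) -> RandomForestClassifier:
    """Random search then a local grid refinement, maximizing held-out AUROC.

    With ``search_budget=1`` the default configuration is fit directly.  The
    search trace (configuration, validation AUROC) is stored on the returned
    classifier as ``search_trace_``.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in labels")
    Xa = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    trace: list[tuple[dict, float]] = []

    if search_budget <= 1:
        best = dict(_BASE_PARAMS)
    else:
        Xtr, Xval, ytr, yval = train_test_split(
            Xa, y, test_size=val_fraction, stratify=y,
            random_state=int(rng.integers(2**31)))

        def evaluate(params: dict) -> float:
            clf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
            clf.fit(Xtr, ytr)
            return float(roc_auc_score(yval, clf.predict_proba(Xval)[:, 1]))

        # stage 1: random search
        candidates = [dict(_BASE_PARAMS)]
        n_random = max(search_budget // 2, 1)
        for _ in range(n_random):
            candidates.append(dict(
                n_estimators=int(rng.choice([50, 100, 200])),
                max_depth=[None, 5, 10, 20][rng.integers(4)],
                min_samples_leaf=int(rng.choice([1, 2, 5, 10])),
                max_features=["sqrt", "log2", 0.5][rng.integers(3)],
            ))
        for params in candidates:
            trace.append((params, evaluate(params)))
        best = max(trace, key=lambda t: t[1])[0]
        # stage 2: grid around the random-search winner
        remaining = search_budget - len(candidates)
        if remaining > 0:
            grid = []
            for leaf in {max(1, best["min_samples_leaf"] // 2),
                         best["min_samples_leaf"],
                         best["min_samples_leaf"] * 2}:
                for n_est in {best["n_estimators"], best["n_estimators"] * 2}:
                    grid.append({**best, "min_samples_leaf": leaf,
                                 "n_estimators": n_est})
            for params in grid[:remaining]:
                trace.append((params, evaluate(params)))
            best = max(trace, key=lambda t: t[1])[0]

    final = RandomForestClassifier(random_state=seed, n_jobs=1, **best)
    final.fit(Xa, y)
    final.search_trace_ = trace
    return final


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationTable:
    """Bin-wise mapping from raw classifier score to calibrated EMS.

    ``ems_value`` per bin is the positive fraction ``f`` rescaled from the
    training prevalence ``train_rate`` (pi_t) to the genome-wide base rate
    ``base_rate`` (pi) by prior odds, then made monotone non-decreasing by
    pooling adjacent violators.
    """

    bin_edges: np.ndarray          # len B+1, increasing, spanning [0, 1]
    pos_fraction: np.ndarray       # len B
    ems_value: np.ndarray          # len B, monotone non-decreasing
    counts: np.ndarray             # len B, labeled pairs per bin
    base_rate: float
    train_rate: float

    def lookup(self, raw_scores: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.bin_edges[1:-1], raw_scores, side="right")
        return self.ems_value[idx]


def _prevalence_rescale(f: np.ndarray, pi: float, pi_t: float) -> np.ndarray:
    """Map a positive fraction at prevalence pi_t to one at prevalence pi."""
    num = f * pi / pi_t
    den = num + (1.0 - f) * (1.0 - pi) / (1.0 - pi_t)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / den, 0.0)
    return out


def _pool_adjacent_violators(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted isotonic (non-decreasing) projection by PAVA."""
    blocks = [[v, w, 1] for v, w in zip(values.astype(float), weights.astype(float))]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] > blocks[i + 1][0] + 1e-15:
            v1, w1, n1 = blocks[i]
            v2, w2, n2 = blocks.pop(i + 1)
            w = w1 + w2
            blocks[i] = [(v1 * w1 + v2 * w2) / w if w > 0 else (v1 + v2) / 2, w, n1 + n2]
            i = max(i - 1, 0)
        else:
            i += 1
    return np.concatenate([[v] * n for v, _, n in blocks])


def calibrate_to_ems(
    raw_scores: np.ndarray,
    labels: np.ndarray,
    base_rate: float | None = None,
    n_bins: int = 20,
    min_bin_count: int = 50,
    rescale: bool = True,
) -> CalibrationTable:
    """Build the raw-score -> EMS calibration table from held-out labeled pairs.

    Bins are raw-score quantile bins; adjacent bins with fewer than
    ``min_bin_count`` labeled pairs are merged.  With ``rescale=False`` the
    per-bin positive fraction is used directly (no prevalence adjustment).
    """
    raw_scores = np.asarray(raw_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if raw_scores.size == 0:
        raise ValueError("empty held-out set")
    pi_t = float(labels.mean())
    if not 0.0 < pi_t < 1.0:
        raise ValueError("held-out labels must contain both classes")
    pi = pi_t if base_rate is None else float(base_rate)
    if not 0.0 < pi < 1.0:
        raise ValueError(f"base rate must be in (0, 1), got {pi}")

    qs = np.quantile(raw_scores, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    edges[0], edges[-1] = 0.0, 1.0
    if edges.size < 2:
        edges = np.array([0.0, 1.0])
    # merge underpopulated adjacent bins
    while edges.size > 2:
        idx = np.searchsorted(edges[1:-1], raw_scores, side="right")
        counts = np.bincount(idx, minlength=edges.size - 1)
        small = np.flatnonzero(counts < min_bin_count)
        if small.size == 0:
            break
        b = int(small[0])
        drop = b + 1 if b < edges.size - 2 else b  # merge right, last merges left
        edges = np.delete(edges, drop)
    idx = np.searchsorted(edges[1:-1], raw_scores, side="right")
    n_b = edges.size - 1
    counts = np.bincount(idx, minlength=n_b).astype(int)
    pos = np.bincount(idx, weights=labels, minlength=n_b)
    with np.errstate(invalid="ignore"):
        f = np.where(counts > 0, pos / np.maximum(counts, 1), 0.0)
    ems = _prevalence_rescale(f, pi, pi_t) if rescale else f.copy()
    ems = np.clip(_pool_adjacent_violators(ems, counts.astype(float)), 0.0, 1.0)
    return CalibrationTable(edges, f, ems, counts, pi, pi_t)


# ---------------------------------------------------------------------------
# the trained model and scoring
# ---------------------------------------------------------------------------

@dataclass
class EMSModel:
    """Trained classifier + selected features + calibration table."""

    classifier: RandomForestClassifier
    selected_features: list[str]
    calibration: CalibrationTable
    holdout_chrom: str | None = None
    seed: int | None = None

    @property
    def feature_importances(self) -> pd.Series:
        imp = self.classifier.feature_importances_
        return pd.Series(imp, index=self.selected_features)

    def save(self, outdir: str) -> None:
        import pickle

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "classifier.pkl"), "wb") as fh:
            pickle.dump(self.classifier, fh)
        cal = self.calibration
        pd.DataFrame({
            "bin_lo": cal.bin_edges[:-1], "bin_hi": cal.bin_edges[1:],
            "pos_fraction": cal.pos_fraction, "ems_value": cal.ems_value,
            "count": cal.counts,
        }).to_csv(os.path.join(outdir, "calibration.tsv"), sep="\t", index=False)
        meta = {"selected_features": self.selected_features,
                "holdout_chrom": self.holdout_chrom, "seed": self.seed,
                "base_rate": cal.base_rate, "train_rate": cal.train_rate}
        with open(os.path.join(outdir, "metadata.json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, outdir: str) -> "EMSModel":
        import pickle

        with open(os.path.join(outdir, "classifier.pkl"), "rb") as fh:
            clf = pickle.load(fh)
        with open(os.path.join(outdir, "metadata.json")) as fh:
            meta = json.load(fh)
        tab = pd.read_csv(os.path.join(outdir, "calibration.tsv"), sep="\t")
        cal = CalibrationTable(
            np.append(tab["bin_lo"].to_numpy(), tab["bin_hi"].iloc[-1]),
            tab["pos_fraction"].to_numpy(), tab["ems_value"].to_numpy(),
            tab["count"].to_numpy(int), meta["base_rate"], meta["train_rate"])
        return cls(clf, meta["selected_features"], cal,
                   meta.get("holdout_chrom"), meta.get("seed"))


def score_pairs(
    model: EMSModel,
    features: pd.DataFrame,
    fixed_tss_bp: float | None = None,
) -> np.ndarray:
    """Calibrated EMS per pair.

    ``fixed_tss_bp`` overrides the distance feature with a constant before
    scoring (episomal-assay mode: reporter constructs place every variant at
    a typical short promoter distance, so distance carries no information).
    """
    missing = [c for c in model.selected_features if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    X = features[model.selected_features].copy()
    if fixed_tss_bp is not None and "tss_distance" in X.columns:
        X["tss_distance"] = float(fixed_tss_bp)
    raw = model.classifier.predict_proba(X.to_numpy(dtype=float))[:, 1]
    return model.calibration.lookup(raw)


def adjust_prior_ratio(weights: np.ndarray, max_ratio: float = 100.0) -> np.ndarray:
    """Floor weights so that max(weights)/min(weights) <= ``max_ratio``.

    Weights below ``max(weights)/max_ratio`` are raised to that floor; the
    top of the prior is preserved.  Idempotent.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if max_ratio <= 1:
        raise ValueError(f"max_ratio must exceed 1, got {max_ratio}")
    floor = w.max() / max_ratio
    return np.maximum(w, floor)


def feature_importance_report(model: EMSModel) -> tuple[pd.Series, pd.Series]:
    """Per-feature MDI importances and per-category shares (both sum to 1)."""
    if not hasattr(model.classifier, "feature_importances_"):
        raise ValueError("model is not trained")
    per_feature = model.feature_importances
    classes = feature_classes(per_feature.index)
    per_category = per_feature.groupby(per_feature.index.map(classes)).sum()
    return per_feature, per_category


# ---------------------------------------------------------------------------
# end-to-end training
# ---------------------------------------------------------------------------

def train_ems_model(
    pairs: pd.DataFrame,
    features: pd.DataFrame,
    holdout_chrom: str | None = None,
    rule: LabelRule | None = None,
    k_features: int | None = None,
    n_bins: int = 20,
    base_rate: float | None = None,
    search_budget: int = 1,
    rescale: bool = True,
    seed: int = 0,
) -> EMSModel:
    """Label, balance, select features, train and calibrate in one call.

    All labeled pairs off the held-out chromosome are used; a random 25%
    (seeded) is reserved to build the calibration table and the classifier
    is trained on the rest, so pairs on the held-out chromosome contribute
    nothing to the model that later scores them.  The default genome-wide
    base rate is #positives / #all pairs in the input.
    """
    rng = np.random.default_rng(seed)
    labels = construct_labels(pairs, rule)
    labeled = labels != "unlabeled"
    y_all = (labels == "positive").astype(int).to_numpy()
    if base_rate is None:
        base_rate = float(y_all.sum()) / len(pairs)

    usable = labeled.to_numpy()
    if holdout_chrom is not None:
        if holdout_chrom not in set(pairs["chrom"]):
            raise ValueError(f"holdout chromosome {holdout_chrom!r} absent")
        usable &= (pairs["chrom"] != holdout_chrom).to_numpy()
    lab_idx = np.flatnonzero(usable)
    if lab_idx.size == 0:
        raise ValueError("no labeled pairs available for training")
    # stratified 25% calibration split so both classes appear on both sides
    cal_parts, tr_parts = [], []
    for cls in (0, 1):
        idx = lab_idx[y_all[lab_idx] == cls]
        rng.shuffle(idx)
        n_cal_cls = max(idx.size // 4, 1) if idx.size else 0
        cal_parts.append(idx[:n_cal_cls])
        tr_parts.append(idx[n_cal_cls:])
    cal_idx = np.concatenate(cal_parts)
    tr_idx = np.concatenate(tr_parts)
    train_mask = np.zeros(len(pairs), dtype=bool)
    train_mask[tr_idx] = True
    cal_mask = np.zeros(len(pairs), dtype=bool)
    cal_mask[cal_idx] = True
    train_mask = pd.Series(train_mask, index=pairs.index)
    cal_mask = pd.Series(cal_mask, index=pairs.index)
    if not cal_mask.any():
        raise ValueError("no labeled pairs available for calibration")

    X_tr = features[train_mask.to_numpy()]
    y_tr = y_all[train_mask.to_numpy()]
    keep = _balanced_subsample(y_tr, rng)
    X_bal, y_bal = X_tr.iloc[keep], y_tr[keep]

    if k_features is None:
        k_features = min(152, features.shape[1])
    sub_seed = int(rng.integers(2**31))
    selected = select_features(X_bal, y_bal, k=k_features, seed=sub_seed)
    clf = tune_and_train(X_bal[selected], y_bal, search_budget=search_budget,
                         seed=sub_seed)
    raw_cal = clf.predict_proba(
        features.loc[cal_mask.to_numpy(), selected].to_numpy(dtype=float))[:, 1]
    cal = calibrate_to_ems(raw_cal, y_all[cal_mask.to_numpy()],
                           base_rate=base_rate, n_bins=n_bins, rescale=rescale)
    return EMSModel(clf, selected, cal, holdout_chrom, seed)
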