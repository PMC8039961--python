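"""Diagnostic-marker evaluation: stratified half splits, ROC/AUC and
panel scoring with a train-only random-forest (or mean-methylation)
scorer, plus a bootstrap confidence interval for the AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["split_half", "roc_auc", "RocCurve", "panel_score",
           "evaluate_panel", "auc_bootstrap_ci"]


def split_half(labels: pd.Series, seed: int) -> tuple[list, list]:
    """Random equal-size train/test split stratified by class.

    ``|train| = ceil(n / 2)`` overall; the split is disjoint, covering, and
    deterministic under the seed.  A class with a single sample cannot be
    stratified and raises."""
    rng = np.random.default_rng(seed)
    counts = labels.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with a single sample cannot be split: "
                         f"{bad}")
    n = len(labels)
    target_train = -(-n // 2)  # ceil
    train: list = []
    test: list = []
    # per-class floor first, then distribute the remainder over odd classes
    leftovers = []
    for cls in sorted(counts.index.astype(str)):
        members = [s for s in labels.index if str(labels[s]) == cls]
        perm = list(rng.permutation(members))
        half = len(perm) // 2
        train.extend(perm[:half])
        if len(perm) % 2:
            leftovers.append(perm[half])
            test.extend(perm[half + 1:])
        else:
            test.extend(perm[half:])
    for s in leftovers:
        if len(train) < target_train:
            train.append(s)
        else:
            test.append(s)
    return train, test


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray,
            pos_label=1) -> RocCurve:
    """ROC curve by threshold sweep and trapezoid AUC; with tied scores this
    equals the rank-average Mann-Whitney statistic ``U / (n1 * n2)``."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    pos = y == pos_label
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, thr = roc_curve(pos.astype(int), s, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auc=float(roc_auc_score(pos.astype(int), s)))


def panel_score(meth: pd.DataFrame, labels: pd.Series, panel_genes: list,
                train_samples: list, model: str = "random_forest",
                seed: int = 0, pos_label="tumor") -> pd.Series:
    """Per-sample panel score from promoter methylation of the panel genes.

    The default scorer is a random-forest class probability fit on the
    train split only (no test leakage); ``model="mean"`` scores by the mean
    panel methylation without any fitting."""
    missing = [g for g in panel_genes if g not in meth.index]
    if missing:
        raise ValueError(f"panel genes without methylation: {missing}")
    X = meth.loc[panel_genes].T  # samples x genes
    if model == "mean":
        return X.mean(axis=1)
    if model != "random_forest":
        raise ValueError(f"unknown scorer {model!r}")
    clf = RandomForestClassifier(n_estimators=200,
                                 random_state=int(seed) % (2 ** 31))
    y_train = (labels.loc[train_samples] == pos_label).astype(int)
    clf.fit(X.loc[train_samples], y_train)
    return pd.Series(clf.predict_proba(X)[:, 1], index=X.index)


def evaluate_panel(meth: pd.DataFrame, labels: pd.Series, panel_genes: list,
                   seed: int = 0, model: str = "random_forest",
                   pos_label="tumor") -> dict:
    """Split, fit on train, report test-split ROC/AUC."""
    train, test = split_half(labels, seed)
    scores = panel_score(meth, labels, panel_genes, train, model=model,
                         seed=seed, pos_label=pos_label)
    curve = roc_auc(scores.loc[test],
                    (labels.loc[test] == pos_label).astype(int))
    return {"train": train, "test": test, "scores": scores,
            "test_auc": curve.auc, "curve": curve}


def auc_bootstrap_ci(scores: pd.Series, labels: pd.Series,
                     n_boot: int = 2000, seed: int = 0,
                     pos_label="tumor", level: float = 0.95) -> tuple:
    """Percentile bootstrap confidence interval for the AUC (resampling
    samples with replacement, stratified draws not enforced)."""
    rng = np.random.default_rng(seed)
    y = (np.asarray(labels) == pos_label).astype(int)
    s = np.asarray(scores, dtype=float)
    n = y.size
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if y[idx].min() == y[idx].max():
            continue
        stats.append(roc_auc_score(y[idx], s[idx]))
    lo, hi = np.quantile(stats, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)
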