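"""Evaluation protocol: stratified 5-fold CV, grid search, metrics.

The outer loop is a stratified k-fold split.  Within each outer fold,
model selection is a grid search trained on 80% of the outer-training
data and scored by AUROC on the remaining 20%; the selected model is
then evaluated once on the untouched test fold.  Reported metrics:
AUROC, accuracy, weighted F1 (WF1), Matthews correlation coefficient
(MCC), sensitivity and specificity.

AUROC is computed as the rank statistic over all positive/negative pairs
(ties get half credit); the thresholded metrics come from the confusion
matrix at the 0.5 decision threshold.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .gnn import ModelConfig, ModelParams, predict, train
from .graphprep import LabeledExample

__all__ = [
    "CVPlan",
    "EvalReport",
    "auroc",
    "compute_metrics",
    "stratified_kfold",
    "grid_search",
    "cross_validate",
    "METRIC_NAMES",
]

METRIC_NAMES = ("auroc", "accuracy", "wf1", "mcc", "sensitivity", "specificity")


def auroc(labels, scores) -> float | None:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a random positive outranks a random
    negative, with ties counted half.  ``None`` (undefined, not 0) when
    only one class is present.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def compute_metrics(labels, probabilities, threshold: float = 0.5) -> dict:
    """The six evaluation metrics from labels and predicted probabilities.

    WF1 is the support-weighted mean of the per-class F1 scores; MCC uses
    the 0 convention when a denominator factor vanishes.  AUROC is
    ``None`` for a single-class label vector.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have the same length")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = tp + tn + fp + fn
    acc = (tp + tn) / n if n else 0.0
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    f1_pos = _f1(tp, fp, fn)
    f1_neg = _f1(tn, fn, fp)
    support_pos, support_neg = tp + fn, tn + fp
    wf1 = (f1_pos * support_pos + f1_neg * support_neg) / n if n else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {
        "auroc": auroc(y, p),
        "accuracy": acc,
        "wf1": wf1,
        "mcc": float(mcc),
        "sensitivity": sens,
        "specificity": spec,
    }


@dataclass
class CVPlan:
    """Outer fold assignment plus per-fold inner 80/20 selection splits.

    ``fold[i]`` is the outer test fold of example i.  For outer fold f,
    ``inner[f] = (fit_idx, val_idx)`` partitions the other folds'
    indices; the test fold never appears in either.
    """

    fold: np.ndarray
    inner: list[tuple[np.ndarray, np.ndarray]]
    k: int
    seed: int

    def test_indices(self, f: int) -> np.ndarray:
        return np.where(self.fold == f)[0]


def stratified_kfold(labels, k: int, seed: int) -> CVPlan:
    """Deterministic stratified k-fold plan with inner 80/20 splits.

    Per-fold class proportions stay within one example of the global
    proportion.  Raises when a class has fewer than ``k`` members.
    """
    y = np.asarray(labels).astype(int)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= {k} members; got class counts {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold[test_idx] = f
    inner = []
    for f in range(k):
        pool = np.where(fold != f)[0]
        fit_idx, val_idx = train_test_split(
            pool, test_size=0.2, random_state=seed * 1000 + f, stratify=y[pool]
        )
        inner.append((np.sort(fit_idx), np.sort(val_idx)))
    return CVPlan(fold=fold, inner=inner, k=k, seed=seed)


def _tie_break_key(cfg: ModelConfig):
    # higher AUROC first; ties: smaller d, then fewer layers, then larger lr
    return (cfg.d, cfg.layers, -cfg.lr)


def grid_search(
    grid: list[ModelConfig],
    fit: list[LabeledExample],
    val: list[LabeledExample],
    seed: int,
) -> tuple[ModelConfig, ModelParams | None, pd.DataFrame]:
    """Train one model per grid point on ``fit``, score AUROC on ``val``,
    return the argmax (with its trained parameters and a selection table).

    A one-point grid is returned as-is without training.  Ties are broken
    toward the smallest embedding size, then the fewest layers, then the
    largest learning rate.
    """
    if not grid:
        raise ValueError("empty hyper-parameter grid")
    if len(grid) == 1:
        return replace(grid[0], seed=seed), None, pd.DataFrame({"variant": [grid[0].variant], "selected": [True]})
    rows = []
    results: list[tuple[float, ModelConfig, ModelParams]] = []
    for cfg in grid:
        cfg = replace(cfg, seed=seed)
        params, history = train(cfg, fit, val)
        score = max(h["val_auroc"] for h in history)
        results.append((score, cfg, params))
        rows.append({"variant": cfg.variant, "d": cfg.d, "layers": cfg.layers, "lr": cfg.lr, "val_auroc": score})
    best_score = max(s for s, _, _ in results)
    candidates = [(cfg, p) for s, cfg, p in results if s == best_score]
    best_cfg, best_params = min(candidates, key=lambda t: _tie_break_key(t[0]))
    table = pd.DataFrame(rows)
    table["selected"] = [
        (r["d"], r["layers"], r["lr"]) == (best_cfg.d, best_cfg.layers, best_cfg.lr) for r in rows
    ]
    return best_cfg, best_params, table


@dataclass
class EvalReport:
    """Per-fold metrics and selected hyper-parameters, plus provenance."""

    folds: list[dict] = field(default_factory=list)
    seed: int = 0
    grid: list[ModelConfig] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.folds)

    def aggregate(self) -> pd.DataFrame:
        """Mean and standard deviation of each metric across folds."""
        df = self.to_frame()
        rows = {}
        for m in METRIC_NAMES:
            vals = df[m].dropna().astype(float)
            rows[m] = f"{vals.mean():.3f} ± {vals.std(ddof=0):.3f}" if len(vals) else "n/a"
        return pd.DataFrame([rows])


def _hash_indices(idx: np.ndarray) -> str:
    return hashlib.sha256(np.sort(np.asarray(idx)).astype(np.int64).tobytes()).hexdigest()[:16]


def cross_validate(
    examples: list[LabeledExample],
    grid: list[ModelConfig],
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvalReport:
    """Stratified k-fold evaluation with inner grid-search selection.

    Hyper-parameters are re-selected per outer fold on an 80/20 split of
    the training folds; the selected model predicts the untouched test
    fold.  The report records, per fold, the selected hyper-parameters,
    the six metrics, and hashes of the train/validation/test index sets
    (so absence of leakage can be audited after the fact).
    """
    y = np.array([e.y for e in examples])
    plan = stratified_kfold(y, k, seed)
    report = EvalReport(seed=seed, grid=list(grid))
    for f in range(k):
        fit_idx, val_idx = plan.inner[f]
        test_idx = plan.test_indices(f)
        fit = [examples[i] for i in fit_idx]
        val = [examples[i] for i in val_idx]
        best_cfg, best_params, _ = grid_search(grid, fit, val, seed=seed * 100 + f)
        if best_params is None:  # one-point grid: still needs a trained model
            best_params, _ = train(best_cfg, fit, val)
        test_prob = predict(best_params, best_cfg, [examples[i].subgraph for i in test_idx])
        metrics = compute_metrics(y[test_idx], test_prob, threshold)
        report.folds.append(
            {
                "fold": f,
                "variant": best_cfg.variant,
                "d": best_cfg.d,
                "layers": best_cfg.layers,
                "lr": best_cfg.lr,
                **metrics,
                "train_hash": _hash_indices(fit_idx),
                "val_hash": _hash_indices(val_idx),
                "test_hash": _hash_indices(test_idx),
                "train_idx": fit_idx.tolist(),
                "val_idx": val_idx.tolist(),
                "test_idx": test_idx.tolist(),
            }
        )
    return report
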