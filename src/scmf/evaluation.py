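"""Cross-validation protocol and ranking metrics.

Known associations (the 1-cells of A) are randomly partitioned into five
equal-sized subsets; each subset is held out in turn, the model is fitted on
the remaining positives, and the held-out positives are ranked against all
pairs that are 0 in the full matrix.  Because unobserved pairs vastly
outnumber known associations, AUPR is the primary metric; AUC and
threshold-based SN/SP/ACC/F are also reported.

Metric conventions (they matter and are easy to get subtly wrong):

* AUPR is tie-grouped average precision: precision/recall are computed at
  every distinct score threshold and integrated step-wise over recall
  (sum of recall increments times precision).  With this convention a
  perfect ranking scores 1 and the worst ranking of a single positive among
  N candidates scores 1/N.
* AUC is the Mann-Whitney statistic: the probability that a random positive
  outranks a random negative, with ties counted 1/2.
* SN/SP/ACC/F need a binarization cutoff; the default rule picks the
  threshold maximizing F over all distinct scores and is recorded in the
  result so reports stay comparable.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import AssociationMatrix, as_array
from .factorization import FitResult, Hyperparameters, fit, predict

__all__ = [
    "FoldPlan",
    "MetricSet",
    "EvaluationReport",
    "make_folds",
    "mask_for_training",
    "precision_recall_points",
    "aupr",
    "auroc",
    "binary_metrics",
    "evaluate_scores",
    "cross_validate",
    "grid_search",
]

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    """Assignment of each known association (cell) to a cross-validation fold."""

    fold_count: int
    cells: np.ndarray  # (q, 2) row/col indices of positive cells
    folds: np.ndarray  # (q,) fold label per cell
    seed: int

    def held_cells(self, fold: int) -> np.ndarray:
        if not 0 <= fold < self.fold_count:
            raise ValueError(f"fold {fold} outside [0, {self.fold_count})")
        return self.cells[self.folds == fold]


@dataclass
class MetricSet:
    """AUPR, AUC and thresholded binary metrics for one evaluation."""

    aupr: float
    auc: float
    sn: float
    sp: float
    acc: float
    f: float
    threshold_rule: str

    def as_dict(self) -> dict:
        return {
            "aupr": self.aupr,
            "auc": self.auc,
            "sn": self.sn,
            "sp": self.sp,
            "acc": self.acc,
            "f": self.f,
        }


@dataclass
class EvaluationReport:
    per_fold: list[MetricSet]
    mean: MetricSet

    def to_frame(self) -> pd.DataFrame:
        rows = [m.as_dict() for m in self.per_fold] + [self.mean.as_dict()]
        idx = [f"fold{i}" for i in range(len(self.per_fold))] + ["mean"]
        return pd.DataFrame(rows, index=idx)


def make_folds(A, fold_count: int = 5, seed: int = 0) -> FoldPlan:
    """Randomly partition the positive cells into near-equal folds.

    Fold sizes differ by at most one; remainder positives land one per fold.
    """
    vals = as_array(A)
    cells = np.argwhere(vals == 1)
    q = len(cells)
    if q < fold_count:
        raise ValueError(f"{q} positives cannot fill {fold_count} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(q)
    folds = np.empty(q, dtype=int)
    folds[perm] = np.arange(q) % fold_count
    return FoldPlan(fold_count=fold_count, cells=cells, folds=folds, seed=seed)


def mask_for_training(A, plan: FoldPlan, held_fold: int):
    """Copy of A with the held-out fold's positive cells zeroed."""
    if isinstance(A, AssociationMatrix):
        out = A.copy()
        held = plan.held_cells(held_fold)
        out.values[held[:, 0], held[:, 1]] = 0.0
        return out
    vals = as_array(A).copy()
    held = plan.held_cells(held_fold)
    vals[held[:, 0], held[:, 1]] = 0.0
    return vals


# ---------------------------------------------------------------------------
# Ranking metrics
# ---------------------------------------------------------------------------

def _check_labels(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("degenerate evaluation: only one class present")


def precision_recall_points(scores, labels):
    """Precision and recall at every distinct score threshold (ties grouped).

    Returns ``(precision, recall, thresholds)`` ordered by decreasing
    threshold; at each threshold t all items with score >= t are predicted
    positive.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    _check_labels(labels)

    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # last index of each tie group of the descending scores
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    tp = np.cumsum(l_sorted)[distinct].astype(float)
    npred = distinct + 1.0
    pos = float(labels.sum())
    precision = tp / npred
    recall = tp / pos
    return precision, recall, s_sorted[distinct]


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (tie-grouped average precision)."""
    precision, recall, _ = precision_recall_points(scores, labels)
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic (ties as 1/2)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    _check_labels(labels)
    ranks = rankdata(scores)
    pos = labels == 1
    p = int(pos.sum())
    n = labels.size - p
    u = ranks[pos].sum() - p * (p + 1) / 2.0
    return float(u / (p * n))


def binary_metrics(scores, labels, rule="max-f"):
    """SN, SP, ACC and F at a binarization cutoff chosen by ``rule``.

    Rules: ``"max-f"`` (default) scans all distinct thresholds and keeps the
    one maximizing F; ``("fixed", t)`` predicts positive at score >= t;
    ``("top", n)`` predicts the n highest scores positive.
    Returns ``(sn, sp, acc, f, rule_description)``.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    _check_labels(labels)
    pos = float(labels.sum())
    neg = float(labels.size - pos)

    order = np.argsort(-scores, kind="mergesort")
    l_sorted = labels[order]
    s_sorted = scores[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    tp_all = np.cumsum(l_sorted).astype(float)

    def metrics_at(tp: float, npred: float):
        fp = npred - tp
        fn = pos - tp
        tn = neg - fp
        sn = tp / pos
        sp = tn / neg
        acc = (tp + tn) / labels.size
        prec = tp / npred if npred > 0 else 0.0
        f = 2 * prec * sn / (prec + sn) if (prec + sn) > 0 else 0.0
        return sn, sp, acc, f

    if rule == "max-f":
        tp = tp_all[distinct]
        npred = distinct + 1.0
        fs = np.where(
            (tp / np.maximum(npred, 1) + tp / pos) > 0,
            2 * (tp / npred) * (tp / pos) / np.maximum(tp / npred + tp / pos, 1e-300),
            0.0,
        )
        best = int(np.argmax(fs))  # first (highest threshold) on ties
        sn, sp, acc, f = metrics_at(tp[best], npred[best])
        desc = f"max-f (threshold={s_sorted[distinct][best]:.6g})"
    elif isinstance(rule, tuple) and rule[0] == "fixed":
        thr = float(rule[1])
        npred = float((scores >= thr).sum())
        tp = float(labels[scores >= thr].sum())
        sn, sp, acc, f = metrics_at(tp, npred)
        desc = f"fixed (threshold={thr:.6g})"
    elif isinstance(rule, tuple) and rule[0] == "top":
        n_top = int(rule[1])
        if not 1 <= n_top <= labels.size:
            raise ValueError(f"top-n cutoff {n_top} out of range")
        tp = float(tp_all[n_top - 1])
        sn, sp, acc, f = metrics_at(tp, float(n_top))
        desc = f"top-{n_top}"
    else:
        raise ValueError(f"unknown threshold rule: {rule!r}")
    return sn, sp, acc, f, desc


def evaluate_scores(scores, labels, rule="max-f") -> MetricSet:
    """All six metrics for one score/label vector."""
    sn, sp, acc, f, desc = binary_metrics(scores, labels, rule)
    return MetricSet(
        aupr=aupr(scores, labels),
        auc=auroc(scores, labels),
        sn=sn,
        sp=sp,
        acc=acc,
        f=f,
        threshold_rule=desc,
    )


# ---------------------------------------------------------------------------
# Cross-validation and grid search
# ---------------------------------------------------------------------------

def _mean_metrics(per_fold: Sequence[MetricSet]) -> MetricSet:
    arr = pd.DataFrame([m.as_dict() for m in per_fold]).mean()
    return MetricSet(
        aupr=float(arr["aupr"]),
        auc=float(arr["auc"]),
        sn=float(arr["sn"]),
        sp=float(arr["sp"]),
        acc=float(arr["acc"]),
        f=float(arr["f"]),
        threshold_rule=per_fold[0].threshold_rule.split(" (")[0] + " (per fold)",
    )


def cross_validate(
    A,
    Wd,
    Ws,
    hp: Hyperparameters | None = None,
    plan: FoldPlan | None = None,
    fold_count: int = 5,
    seed: int = 0,
    rule="max-f",
) -> EvaluationReport:
    """Hold out each fold of positives, refit, and score the held-out cells.

    For every fold the evaluated cells are the held-out positives plus all
    cells that are 0 in the full matrix (training positives are excluded);
    the negatives are never subsampled, reflecting the real class imbalance.
    A drug or disease may lose all its training positives in some fold; the
    factorization still produces scores for it, so the fold proceeds with a
    warning.
    """
    hp = hp or Hyperparameters()
    full = as_array(A)
    plan = plan or make_folds(full, fold_count=fold_count, seed=seed)
    per_fold = []
    for f_idx in range(plan.fold_count):
        train = mask_for_training(full, plan, f_idx)
        empty_rows = int((train.sum(axis=1) == 0).sum())
        empty_cols = int((train.sum(axis=0) == 0).sum())
        if empty_rows or empty_cols:
            warnings.warn(
                f"fold {f_idx}: {empty_rows} drugs / {empty_cols} diseases have "
                "no training positives"
            )
        fold_hp = replace(hp, seed=int(hp.seed + f_idx))
        result = fit(train, Wd, Ws, fold_hp)
        scores = predict(result.factors)
        eval_mask = train == 0  # held-out positives and all true zeros
        m = evaluate_scores(scores[eval_mask], full[eval_mask], rule)
        logger.info("fold %d: AUPR=%.4f AUC=%.4f", f_idx, m.aupr, m.auc)
        per_fold.append(m)
    return EvaluationReport(per_fold=per_fold, mean=_mean_metrics(per_fold))


def grid_search(
    A,
    Wd,
    Ws,
    k_fractions: Sequence[float],
    mus: Sequence[float],
    lams: Sequence[float],
    fold_count: int = 5,
    seed: int = 0,
    hp_base: Hyperparameters | None = None,
    rule="max-f",
) -> pd.DataFrame:
    """Exhaustive cross-validated grid over (k_fraction, mu, lam).

    One fold plan (fixed seed) is shared by all combinations so rows are
    comparable.  Returns a DataFrame with per-combination mean AUPR/AUC and
    a ``best`` flag on the unique argmax-AUPR row (first on exact ties).
    """
    if not (len(k_fractions) and len(mus) and len(lams)):
        raise ValueError("all three grids must be nonempty")
    hp_base = hp_base or Hyperparameters()
    full = as_array(A)
    plan = make_folds(full, fold_count=fold_count, seed=seed)
    rows = []
    for kf, mu, lam in itertools.product(k_fractions, mus, lams):
        hp = replace(hp_base, k=None, k_fraction=kf, mu=mu, lam=lam)
        report = cross_validate(full, Wd, Ws, hp, plan=plan, rule=rule)
        rows.append(
            {
                "k_fraction": kf,
                "mu": mu,
                "lam": lam,
                "aupr": report.mean.aupr,
                "auc": report.mean.auc,
            }
        )
        logger.info(
            "grid k=%.2f mu=%g lam=%g -> AUPR %.4f", kf, mu, lam, rows[-1]["aupr"]
        )
    table = pd.DataFrame(rows)
    table["best"] = False
    table.loc[table["aupr"].idxmax(), "best"] = True
    return table
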