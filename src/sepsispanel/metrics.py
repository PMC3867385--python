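"""Diagnostic performance measures, averaged ROC curves and validation sweeps.

Confusion-matrix measures are the five standard ones: true positive rate
TPR = TP/(TP+FN), true negative rate TNR = TN/(TN+FP), positive and
negative predictive values PPV = TP/(TP+FP), NPV = TN/(TN+FN), and accuracy
ACC = (TP+TN)/n.  A zero denominator makes a measure undefined; undefined
values propagate as NaN and are excluded (and counted) when averaging over
divisions — silently reporting 0 would bias the summaries.

ROC curves use the inclusive ``score >= threshold`` positivity convention so
the deployed classifier's operating point (threshold 0) lies exactly on its
own curve.  Curves from repeated divisions are averaged vertically: each is
linearly interpolated onto a common FPR grid and the mean and SD of TPR are
reported per grid point.

``exhaustive_validation`` re-evaluates every biomarker combination of each
requested size on one shared set of learning/test divisions and reports the
rank of the CCA-selected subset per measure — the rank form of the claim
that the selected panel is at or near the exhaustive optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

MEASURE_NAMES: tuple[str, ...] = ("TPR", "TNR", "PPV", "NPV", "ACC")


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts with +1 as the positive (septic) class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Count TP/FP/TN/FN for ±1 labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == -1) & (y_pred == 1)).sum()),
        tn=int(((y_true == -1) & (y_pred == -1)).sum()),
        fn=int(((y_true == 1) & (y_pred == -1)).sum()),
    )


def measures(c: ConfusionCounts) -> dict[str, float]:
    """TPR, TNR, PPV, NPV, ACC; NaN where a denominator is zero."""
    if c.n == 0:
        raise ValueError("cannot compute measures on zero samples")

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "TPR": _ratio(c.tp, c.tp + c.fn),
        "TNR": _ratio(c.tn, c.tn + c.fp),
        "PPV": _ratio(c.tp, c.tp + c.fp),
        "NPV": _ratio(c.tn, c.tn + c.fn),
        "ACC": (c.tp + c.tn) / c.n,
    }


@dataclass
class PerformanceSummary:
    """Mean ± SD of the five measures over R random divisions."""

    method: str
    subset: tuple[str, ...]
    R: int
    mean: dict[str, float]
    sd: dict[str, float]
    n_undefined: dict[str, int]
    weights_mean: np.ndarray | None = None
    weights_se: np.ndarray | None = None
    roc_curves: list = field(default_factory=list)

    @classmethod
    def from_divisions(cls, per_division: list[dict[str, float]], *,
                       method: str, subset: Sequence[str],
                       weights_mean: np.ndarray | None = None,
                       weights_se: np.ndarray | None = None,
                       ) -> "PerformanceSummary":
        R = len(per_division)
        mean: dict[str, float] = {}
        sd: dict[str, float] = {}
        n_undef: dict[str, int] = {}
        for m in MEASURE_NAMES:
            vals = np.array([d[m] for d in per_division], dtype=float)
            ok = np.isfinite(vals)
            n_undef[m] = int((~ok).sum())
            if ok.any():
                mean[m] = float(vals[ok].mean())
                sd[m] = float(vals[ok].std(ddof=1)) if ok.sum() > 1 else 0.0
            else:
                mean[m] = float("nan")
                sd[m] = float("nan")
        return cls(method=method, subset=tuple(subset), R=R, mean=mean,
                   sd=sd, n_undefined=n_undef, weights_mean=weights_mean,
                   weights_se=weights_se)

    def to_row(self) -> dict:
        row: dict = {"method": self.method,
                     "subset": ", ".join(self.subset), "R": self.R}
        for m in MEASURE_NAMES:
            row[m] = self.mean[m]
            row[f"{m}_sd"] = self.sd[m]
            if self.n_undefined[m]:
                row[f"{m}_n_undefined"] = self.n_undefined[m]
        return row


def roc_curve(scores: np.ndarray, y_true: np.ndarray,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Single-division ROC by sweeping the threshold over distinct scores.

    Positivity is ``score >= threshold`` (the deployed rule's convention).
    Returns (fpr, tpr, thresholds, auc); thresholds start at +inf (no
    positives) and the trapezoid rule gives the AUC.  Constant scores
    degenerate to the two-point chance diagonal with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if np.unique(y_true).size < 2:
        raise ValueError("both classes must be present")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == -1).sum())
    if np.unique(scores).size == 1:
        warnings.warn("constant scores: ROC degenerates to the chance "
                      "diagonal", UserWarning, stacklevel=2)
        fpr = np.array([0.0, 1.0])
        tpr = np.array([0.0, 1.0])
        return fpr, tpr, np.array([np.inf, scores[0]]), 0.5
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    pos_sorted = (y_true[order] == 1).astype(float)
    tp_cum = np.cumsum(pos_sorted)
    fp_cum = np.cumsum(1.0 - pos_sorted)
    # last index of each distinct score = the ">= threshold" cut
    distinct = np.nonzero(np.diff(s_sorted, append=-np.inf))[0]
    tpr = np.concatenate([[0.0], tp_cum[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fp_cum[distinct] / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[distinct]])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc


@dataclass
class ROCCurve:
    """Vertically averaged ROC over R divisions on a common FPR grid."""

    fpr_grid: np.ndarray
    tpr_mean: np.ndarray
    tpr_sd: np.ndarray
    auc_mean: float

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr_grid, "tpr_mean": self.tpr_mean,
                             "tpr_sd": self.tpr_sd})


def average_roc(curves: Sequence[tuple], n_grid: int = 101) -> ROCCurve:
    """Average single-division ROC curves vertically on a common FPR grid.

    Each curve (fpr, tpr, thresholds, auc) is linearly interpolated onto
    ``n_grid`` equispaced FPR points; the mean and SD of TPR are taken per
    point, and ``auc_mean`` is the mean of the member AUCs.
    """
    if len(curves) == 0:
        raise ValueError("need at least one curve")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.stack([np.interp(grid, c[0], c[1]) for c in curves])
    sd = tprs.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(n_grid)
    return ROCCurve(
        fpr_grid=grid,
        tpr_mean=tprs.mean(axis=0),
        tpr_sd=sd,
        auc_mean=float(np.mean([c[3] for c in curves])),
    )


def univariate_pvalues(X: np.ndarray, y: np.ndarray,
                       names: Sequence[str] | None = None,
                       test: str = "welch") -> pd.DataFrame:
    """Two-sample septic-vs-nonseptic test per biomarker.

    ``test`` is ``'welch'`` (unequal-variance t, the default) or
    ``'mannwhitney'``.  A biomarker constant in both groups is degenerate:
    p = 1 with a flag.  The test name is reported alongside every p-value.
    """
    from scipy import stats

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if test not in ("welch", "mannwhitney"):
        raise ValueError("test must be 'welch' or 'mannwhitney'")
    pos = X[y == 1]
    neg = X[y == -1]
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ValueError("both groups need at least 2 samples")
    p = X.shape[1]
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    rows = []
    for j in range(p):
        a, b = pos[:, j], neg[:, j]
        degenerate = np.unique(np.concatenate([a, b])).size == 1
        if degenerate:
            stat, pval = float("nan"), 1.0
        elif test == "welch":
            stat, pval = stats.ttest_ind(a, b, equal_var=False)
        else:
            stat, pval = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"biomarker": names[j], "statistic": float(stat),
                     "pvalue": float(pval), "test": test,
                     "degenerate": degenerate})
    return pd.DataFrame(rows)


@dataclass
class ValidationSweep:
    """Every-combination performance per subset size, with selected-subset ranks."""

    per_k: dict[int, list[PerformanceSummary]]
    selected: dict[int, tuple[str, ...]]
    ranks: dict[int, dict[str, int]]
    R: int
    B: int

    def to_records(self) -> list[dict]:
        recs = []
        for k, summaries in self.per_k.items():
            for s in summaries:
                rec = s.to_row()
                rec["k"] = k
                rec["is_selected"] = tuple(s.subset) == self.selected[k]
                recs.append(rec)
        return recs


def _rank_of(value: float, values: np.ndarray) -> int:
    """Competition rank of ``value`` among ``values`` (1 = best/largest)."""
    if np.isnan(value):
        return int(np.isfinite(values).sum()) + 1
    return int((values > value).sum()) + 1


def exhaustive_validation(dataset, k_range: Sequence[int], R: int, B: int,
                          seed: int, *, scale: float = 1.0,
                          selected: dict[int, Sequence[str]] | None = None,
                          ) -> ValidationSweep:
    """Bagged-SSVM performance of every biomarker combination per size k.

    All C(p, k) subsets are evaluated with ``repeated_evaluation`` on the
    same R divisions (paired comparison).  ``selected`` maps k to the
    subset whose rank is wanted (default: the exhaustive-CCA winner per k,
    recomputed here); ranks are competition ranks of the subset's mean for
    each measure, 1 = best.
    """
    from .classifiers import make_divisions, repeated_evaluation
    from .preprocess import standardize
    from .selection import best_subsets

    p = len(dataset.names)
    if p > 12:
        raise ValueError(f"p={p} exceeds the exhaustive-validation guard (12)")
    ks = sorted(set(int(k) for k in k_range))
    divisions = make_divisions(dataset.y, R, seed)
    if selected is None:
        sm = standardize(dataset.X, names=dataset.names)
        path = best_subsets(sm.Xtilde, dataset.y, k_range=ks,
                            names=dataset.names)
        selected = {sc.k: tuple(dataset.names[j] for j in sc.indices)
                    for sc in path.best}
    else:
        selected = {int(k): tuple(v) for k, v in selected.items()}

    per_k: dict[int, list[PerformanceSummary]] = {}
    ranks: dict[int, dict[str, int]] = {}
    for k in ks:
        summaries = []
        for idx in combinations(range(p), k):
            summaries.append(repeated_evaluation(
                dataset, feature_subset=list(idx), R=R, B=B, seed=seed,
                scale=scale, divisions=divisions))
        per_k[k] = summaries
        sel = selected[k]
        sel_summary = next(s for s in summaries if tuple(s.subset) == sel)
        ranks[k] = {}
        for m in MEASURE_NAMES:
            vals = np.array([s.mean[m] for s in summaries])
            ranks[k][m] = _rank_of(sel_summary.mean[m], vals)
    return ValidationSweep(per_k=per_k, selected=selected, ranks=ranks,
                           R=R, B=B)
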