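"""Exhaustive canonical-correlation subset selection and forward selection.

With a single outcome (the ±1 septic label), the canonical correlation
between the label and a biomarker subset reduces to the multiple correlation
coefficient: the maximal Pearson correlation between the label and any
linear combination of the subset's columns.  We compute it from the
cross-covariance system via a (pseudo-)inverse on centered data, which is
mathematically identical to the two-set CCA formulation when one set is
univariate and numerically stabler than the generalized eigenproblem (the
eigenproblem route is retained as a cross-check oracle in the test suite).

``best_subsets`` enumerates all C(p, k) subsets per k — a global, not
greedy, search — and reports the enter/leave path between consecutive
winners; ``forward_selection`` is the greedy residual-correlation
comparator, which can differ from the exhaustive optimum when jointly
informative variables (suppressor structure) are present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

#: Enumeration guard: C(p, k) growth makes exhaustive search unreasonable
#: beyond this many candidate biomarkers.
MAX_EXHAUSTIVE_P = 25


@dataclass
class SubsetCorrelation:
    """Best subset of size k with its canonical correlation."""

    k: int
    indices: tuple[int, ...]
    rho: float

    def __post_init__(self) -> None:
        self.indices = tuple(sorted(self.indices))
        if len(self.indices) != self.k:
            raise ValueError("indices must have exactly k entries")


@dataclass
class SelectionPath:
    """Per-k winners with enter/leave annotations and the greedy order."""

    best: list[SubsetCorrelation]
    enter: list[tuple[str, ...]]
    leave: list[tuple[str, ...]]
    names: tuple[str, ...]
    fs_order: tuple[str, ...] = field(default_factory=tuple)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for i, sc in enumerate(self.best):
            rows.append({
                "k": sc.k,
                "correlation": sc.rho,
                "enter": ", ".join(self.enter[i]),
                "leave": ", ".join(self.leave[i]),
                "forward_selection": self.fs_order[i] if i < len(self.fs_order) else "",
                "subset": ", ".join(self.names[j] for j in sc.indices),
            })
        return pd.DataFrame(rows)


def _rho_from_cov(C_xx: np.ndarray, c_xy: np.ndarray, var_y: float) -> float:
    """Multiple correlation from covariance blocks, pseudo-inverse safe."""
    if var_y <= 0:
        raise ValueError("label has zero variance (single class?)")
    try:
        beta = np.linalg.solve(C_xx, c_xy)
    except np.linalg.LinAlgError:
        beta = np.linalg.pinv(C_xx) @ c_xy
    r2 = float(c_xy @ beta) / var_y
    # pinv fallback can slightly overshoot on rank-deficient systems
    if not np.isfinite(r2) or r2 < 0:
        r2 = max(0.0, float(c_xy @ (np.linalg.pinv(C_xx) @ c_xy)) / var_y)
    return float(np.clip(np.sqrt(max(r2, 0.0)), 0.0, 1.0))


def canonical_correlation(X_S: np.ndarray, y: np.ndarray) -> float:
    """Canonical correlation between a label and a biomarker submatrix.

    Equals the multiple correlation coefficient of ``y`` on the columns of
    ``X_S`` (intercept implicit via centering).  Rank-deficient submatrices
    are handled by pseudo-inverse; the result is clipped to [0, 1].
    """
    X_S = np.asarray(X_S, dtype=float)
    if X_S.ndim == 1:
        X_S = X_S[:, None]
    y = np.asarray(y, dtype=float)
    n, k = X_S.shape
    if n <= k:
        raise ValueError(f"need n > k (got n={n}, k={k})")
    if np.unique(y).size < 2:
        raise ValueError("y must contain both classes")
    Xc = X_S - X_S.mean(axis=0)
    yc = y - y.mean()
    C_xx = Xc.T @ Xc
    c_xy = Xc.T @ yc
    return _rho_from_cov(C_xx, c_xy, float(yc @ yc))


def best_subsets(Xtilde: np.ndarray, y: np.ndarray,
                 k_range: Sequence[int] | None = None,
                 names: Sequence[str] | None = None) -> SelectionPath:
    """Globally optimal biomarker subset per size k by full enumeration.

    For each k the subset maximizing the canonical correlation with the
    label is found over all C(p, k) combinations (lexicographic order,
    strict improvement, so ties resolve to the first-seen, lexicographically
    smallest index tuple).  Enter/leave columns are the set differences
    between consecutive winners.
    """
    Xtilde = np.asarray(Xtilde, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xtilde.shape
    if p > MAX_EXHAUSTIVE_P:
        raise ValueError(
            f"p={p} exceeds the exhaustive-enumeration guard "
            f"({MAX_EXHAUSTIVE_P}); use forward_selection for a greedy path")
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    names = tuple(names)
    if k_range is None:
        k_range = range(1, p + 1)
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 1 or k > p for k in ks):
        raise ValueError("k_range must be a subset of 1..p")

    # One pass over the Gram blocks: every subset's rho needs only the
    # corresponding covariance submatrix.
    Xc = Xtilde - Xtilde.mean(axis=0)
    yc = y - y.mean()
    C = Xc.T @ Xc
    c = Xc.T @ yc
    var_y = float(yc @ yc)

    best: list[SubsetCorrelation] = []
    for k in ks:
        best_rho = -np.inf
        best_idx: tuple[int, ...] = ()
        for idx in combinations(range(p), k):
            ii = np.asarray(idx)
            rho = _rho_from_cov(C[np.ix_(ii, ii)], c[ii], var_y)
            if rho > best_rho:
                best_rho = rho
                best_idx = idx
        best.append(SubsetCorrelation(k=k, indices=best_idx, rho=best_rho))

    enter: list[tuple[str, ...]] = []
    leave: list[tuple[str, ...]] = []
    prev: set[int] = set()
    for sc in best:
        cur = set(sc.indices)
        enter.append(tuple(names[j] for j in sorted(cur - prev)))
        leave.append(tuple(names[j] for j in sorted(prev - cur)))
        prev = cur

    fs = forward_selection(Xtilde, y, names=names)
    return SelectionPath(best=best, enter=enter, leave=leave, names=names,
                         fs_order=fs)


def forward_selection(Xtilde: np.ndarray, y: np.ndarray,
                      names: Sequence[str] | None = None) -> tuple[str, ...]:
    """Greedy forward selection by absolute correlation with the residual.

    At each step the residual is the label minus its least-squares
    projection onto the selected columns (plus intercept); the next
    biomarker maximizes the absolute Pearson correlation with that residual.
    Ties break lexicographically on the column index; a numerically zero
    residual appends the remaining biomarkers in lexicographic order with a
    warning.
    """
    Xtilde = np.asarray(Xtilde, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xtilde.shape
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    names = tuple(names)
    Xc = Xtilde - Xtilde.mean(axis=0)
    resid = y - y.mean()
    order: list[int] = []
    remaining = list(range(p))
    col_norms = np.sqrt((Xc ** 2).sum(axis=0))
    for _ in range(p):
        rnorm = float(np.sqrt(resid @ resid))
        if rnorm < 1e-12:
            warnings.warn("residual is numerically zero; remaining order is "
                          "lexicographic", UserWarning, stacklevel=2)
            order.extend(remaining)
            break
        rc = resid - resid.mean()
        rcn = float(np.sqrt(rc @ rc))
        best_j, best_val = remaining[0], -np.inf
        for j in remaining:
            if col_norms[j] == 0 or rcn == 0:
                val = 0.0
            else:
                val = abs(float(Xc[:, j] @ rc)) / (col_norms[j] * rcn)
            if val > best_val:
                best_val, best_j = val, j
        order.append(best_j)
        remaining.remove(best_j)
        # refresh residual: project y on selected columns + intercept
        A = np.column_stack([np.ones(n)] + [Xtilde[:, j] for j in order])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
    return tuple(names[j] for j in order)


def groupwise_correlations(
    X: np.ndarray, y: np.ndarray, names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Pairwise biomarker correlations within the septic and nonseptic groups.

    Returns (septic p×p, nonseptic p×p, meta); the meta dict carries the
    biomarker ordering by |correlation with the label| (ascending, for
    heatmap axes) and flags for any constant-within-group biomarker, whose
    correlations are reported as 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    names = tuple(names)
    out = []
    flagged: dict[str, list[str]] = {}
    for label, tag in ((1, "septic"), (-1, "nonseptic")):
        G = X[y == label]
        if G.shape[0] < 3:
            raise ValueError(f"{tag} group has fewer than 3 records")
        sd = G.std(axis=0, ddof=1)
        flagged[tag] = [names[j] for j in np.nonzero(sd == 0)[0]]
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.corrcoef(G, rowvar=False)
        # constant columns produce NaN rows; report them as 0 (flagged above)
        M = np.where(np.isfinite(M), M, 0.0)
        np.fill_diagonal(M, 1.0)
        out.append(pd.DataFrame(M, index=list(names), columns=list(names)))
    label_corr = np.array([
        0.0 if X[:, j].std(ddof=1) == 0
        else float(np.corrcoef(X[:, j], y)[0, 1])
        for j in range(p)
    ])
    order = [names[j] for j in np.argsort(np.abs(label_corr))]
    meta = {"order_by_abs_label_corr": order,
            "constant_columns": flagged,
            "label_correlations": dict(zip(names, label_corr.tolist()))}
    return out[0], out[1], meta
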