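"""1-norm sparse SVM via linear programming, bagging, and an L1 logistic comparator.

The sparse support vector machine (SSVM) is the linear soft-margin SVM whose
weight vector is penalized by its 1-norm:

    min_{w, b, xi >= 0}  ||w||_1 + C+ * sum_{i: y_i=+1} xi_i
                                  + C- * sum_{i: y_i=-1} xi_i
    s.t.                 y_i (w . x_i + b) >= 1 - xi_i

The 1-norm induces exact zeros in w (embedded feature selection), and the
split class costs C+, C- absorb unbalanced sample sizes: choosing
C+ N+ = C- N- equalizes the total cost of false positives and false
negatives.  With the split w = u - v (u, v >= 0) the problem is a linear
program, solved here with HiGHS dual simplex so the returned solution is an
optimal vertex.  The bias b is unpenalized.

Around a single fit, the module provides bootstrap aggregation (an ensemble
of SSVMs on resamples of the learning set, aggregated by the mean of their
decision values) and repeated random learning/test divisions (test fraction
1/3, stratified) whose mean/SD performance summaries are the headline
outputs.  Divisions are a deterministic function of (labels, R, seed) only,
so different feature subsets can be compared on the same divisions.

``fit_llr`` is the LASSO logistic comparator, minimized by proximal
gradient (FISTA) with an unpenalized bias.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog
from scipy.special import expit

from .metrics import PerformanceSummary, confusion, measures, roc_curve
from .preprocess import apply_standardization, standardize

logger = logging.getLogger(__name__)


@dataclass
class SSVMProblem:
    """A standardized training problem with split class slack costs."""

    Xtilde: np.ndarray
    y: np.ndarray
    c_pos: float
    c_neg: float

    def __post_init__(self) -> None:
        self.Xtilde = np.asarray(self.Xtilde, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.c_pos <= 0 or self.c_neg <= 0:
            raise ValueError("slack costs must be > 0")
        if set(np.unique(self.y)) != {-1.0, 1.0}:
            raise ValueError("y must contain both classes, coded ±1")
        if self.Xtilde.shape[0] != self.y.shape[0]:
            raise ValueError("X and y length mismatch")

    @property
    def n_pos(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.y == -1).sum())


@dataclass
class LinearDecisionFunction:
    """Score(x) = w . x_tilde + b on the standardized scale.

    ``mu``/``sigma`` freeze the standardization so the function can score
    raw-unit inputs; ``None`` means inputs are already standardized.
    """

    w: np.ndarray
    b: float
    names: tuple[str, ...]
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not np.all(np.isfinite(self.w)) or not np.isfinite(self.b):
            raise ValueError("weights and bias must be finite")
        if len(self.names) != self.w.shape[0]:
            raise ValueError("names and w must have equal length")

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.w.shape[0]:
            raise ValueError(
                f"expected {self.w.shape[0]} features, got {X.shape[1]}")
        if self.mu is not None:
            X = apply_standardization(X, self.mu, self.sigma)
        return X @ self.w + self.b


@dataclass
class SlackVariables:
    """Non-negative slacks ξ at the LP optimum."""

    xi: np.ndarray

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        if np.any(self.xi < -1e-9):
            raise ValueError("slack variables must be non-negative")


@dataclass
class EnsembleClassifier:
    """Bagged ensemble of linear decision functions (mean aggregation)."""

    members: list[LinearDecisionFunction]
    names: tuple[str, ...]
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None
    seed: int | None = None
    n_redraws: int = 0

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("ensemble needs at least one member")

    @property
    def B(self) -> int:
        return len(self.members)

    def decision_values(self, X_raw: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X_raw, dtype=float))
        if X.shape[1] != len(self.names):
            raise ValueError(
                f"expected {len(self.names)} features, got {X.shape[1]}")
        if self.mu is not None:
            X = apply_standardization(X, self.mu, self.sigma)
        scores = np.zeros(X.shape[0])
        for m in self.members:
            scores += X @ m.w + m.b
        return scores / self.B

    def mean_weights(self) -> tuple[np.ndarray, float]:
        W = np.stack([m.w for m in self.members])
        bs = np.array([m.b for m in self.members])
        return W.mean(axis=0), float(bs.mean())


def balanced_costs(n_pos: int, n_neg: int, scale: float = 1.0,
                   ) -> tuple[float, float]:
    """Class costs with equal totals: c_pos*n_pos == c_neg*n_neg exactly.

    Parameterized as c± = scale * n / (2 n±); with balanced classes both
    costs equal ``scale``.  Results are insensitive to the overall scale on
    separable data, which is why scale defaults to 1.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class counts must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    n = n_pos + n_neg
    return scale * n / (2.0 * n_pos), scale * n / (2.0 * n_neg)


def fit_ssvm(problem: SSVMProblem,
             ) -> tuple[LinearDecisionFunction, SlackVariables]:
    """Solve the 1-norm SSVM linear program exactly (HiGHS dual simplex).

    Variables are (u, v, b, ξ) with w = u − v, u, v, ξ >= 0 and b free; the
    margin constraints y_i(w·x_i + b) >= 1 − ξ_i become a sparse
    inequality block.  The LP is always feasible (ξ absorbs violations).
    Returns an optimal vertex solution and its slacks.
    """
    X, y = problem.Xtilde, problem.y
    n, k = X.shape
    cost = np.where(y == 1, problem.c_pos, problem.c_neg)
    c = np.concatenate([np.ones(2 * k), [0.0], cost])
    yX = y[:, None] * X
    A = sp.hstack([
        sp.csr_matrix(-yX), sp.csr_matrix(yX),
        sp.csr_matrix(-y[:, None]), -sp.eye(n, format="csr"),
    ], format="csr")
    res = linprog(c, A_ub=A, b_ub=-np.ones(n),
                  bounds=[(0, None)] * (2 * k) + [(None, None)] + [(0, None)] * n,
                  method="highs-ds", options={"presolve": False})
    if not res.success:
        raise RuntimeError(f"SSVM LP did not converge: {res.message} "
                           f"(status {res.status})")
    u, v = res.x[:k], res.x[k:2 * k]
    w = u - v
    b = float(res.x[2 * k])
    xi = np.maximum(res.x[2 * k + 1:], 0.0)
    names = tuple(f"x{j}" for j in range(k))
    return LinearDecisionFunction(w=w, b=b, names=names), SlackVariables(xi=xi)


def ssvm_objective(problem: SSVMProblem, w: np.ndarray, b: float,
                   xi: np.ndarray | None = None) -> float:
    """Objective value of a (w, b, ξ) triple; ξ defaults to its minimum."""
    w = np.asarray(w, dtype=float)
    if xi is None:
        xi = np.maximum(0.0, 1.0 - problem.y * (problem.Xtilde @ w + b))
    cost = np.where(problem.y == 1, problem.c_pos, problem.c_neg)
    return float(np.abs(w).sum() + cost @ xi)


def bootstrap_indices(rng: np.random.Generator, n: int) -> np.ndarray:
    """One bootstrap resample: n draws with replacement from range(n)."""
    return rng.integers(0, n, size=n)


def bootstrap_bag(
    Xtilde: np.ndarray,
    y: np.ndarray,
    B: int,
    seed: int,
    *,
    scale: float = 1.0,
    names: Sequence[str] | None = None,
    mu: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
    resampler=None,
) -> EnsembleClassifier:
    """Bagged SSVM ensemble on a standardized learning set.

    Each of the B members is fitted on a bootstrap resample (same size,
    with replacement) of the learning set, with balanced costs computed on
    that resample's class counts; a resample missing a class is redrawn and
    logged.  ``resampler(rng, n) -> indices`` is a test hook (identity
    resampling reduces the bag to a single plain fit).  Deterministic under
    ``seed``.
    """
    Xtilde = np.asarray(Xtilde, dtype=float)
    y = np.asarray(y, dtype=float)
    if B < 1:
        raise ValueError("B must be >= 1")
    if np.unique(y).size < 2:
        raise ValueError("learning set must contain both classes")
    n, k = Xtilde.shape
    if names is None:
        names = tuple(f"x{j}" for j in range(k))
    names = tuple(names)
    if resampler is None:
        resampler = bootstrap_indices
    rng = np.random.default_rng(seed)
    members: list[LinearDecisionFunction] = []
    n_redraws = 0
    for _ in range(B):
        while True:
            idx = resampler(rng, n)
            yb = y[idx]
            if (yb == 1).any() and (yb == -1).any():
                break
            n_redraws += 1
            logger.debug("bootstrap resample missing a class; redrawn")
        c_pos, c_neg = balanced_costs(int((yb == 1).sum()),
                                      int((yb == -1).sum()), scale)
        f, _ = fit_ssvm(SSVMProblem(Xtilde[idx], yb, c_pos, c_neg))
        members.append(LinearDecisionFunction(w=f.w, b=f.b, names=names))
    if n_redraws:
        logger.info("redrew %d single-class bootstrap resamples", n_redraws)
    return EnsembleClassifier(members=members, names=names, mu=mu,
                              sigma=sigma, seed=seed, n_redraws=n_redraws)


def predict(ensemble: EnsembleClassifier, X_raw: np.ndarray,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Mean ensemble score and the ±1 diagnosis (positive iff score >= 0)."""
    scores = ensemble.decision_values(X_raw)
    labels = np.where(scores >= 0, 1, -1)
    return scores, labels


def make_divisions(y: np.ndarray, R: int, seed: int,
                   test_fraction: float = 1.0 / 3.0,
                   stratified: bool = True,
                   ) -> list[tuple[np.ndarray, np.ndarray]]:
    """R random learning/test divisions, a function of (y, R, seed) only.

    Stratified by class so small cohorts cannot produce single-class test
    sets; a degenerate draw (possible only unstratified) is redrawn with a
    log entry.  Reusing one division list across feature subsets gives
    paired comparisons.
    """
    y = np.asarray(y)
    n = y.shape[0]
    rng = np.random.default_rng(seed)
    divisions = []
    for _ in range(R):
        while True:
            if stratified:
                test_idx = []
                for cls in (1, -1):
                    cls_idx = np.nonzero(y == cls)[0]
                    perm = rng.permutation(cls_idx)
                    n_test = max(1, int(round(test_fraction * cls_idx.size)))
                    test_idx.append(perm[:n_test])
                test = np.sort(np.concatenate(test_idx))
            else:
                perm = rng.permutation(n)
                test = np.sort(perm[: max(1, int(round(test_fraction * n)))])
            learn = np.setdiff1d(np.arange(n), test)
            if (np.unique(y[test]).size == 2
                    and np.unique(y[learn]).size == 2):
                break
            logger.info("single-class division redrawn")
        divisions.append((learn, test))
    return divisions


def repeated_evaluation(
    dataset,
    feature_subset: Sequence[int] | Sequence[str] | None = None,
    R: int = 100,
    B: int = 1000,
    seed: int = 0,
    *,
    scale: float = 1.0,
    divisions: list[tuple[np.ndarray, np.ndarray]] | None = None,
    method: str = "ssvm",
    llr_lambda: float | None = None,
    leakage_safe: bool = False,
    collect_roc: bool = False,
) -> PerformanceSummary:
    """Mean ± SD performance over R random learning/test divisions.

    ``dataset`` is a ``labeling.LabeledDataset`` (raw-unit X).  Default
    standardization is fitted once on all cases before splitting, matching
    the original analysis; ``leakage_safe=True`` refits it on each learning
    set.  Per division: a bagged SSVM (or a single LASSO-logistic fit when
    ``method='llr'``) is trained on the learning set and evaluated on the
    held-out third.  Pass a shared ``divisions`` list to compare feature
    subsets on identical splits.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if method not in ("ssvm", "llr"):
        raise ValueError("method must be 'ssvm' or 'llr'")
    X_all = np.asarray(dataset.X, dtype=float)
    y = np.asarray(dataset.y, dtype=float)
    all_names = tuple(dataset.names)

    if feature_subset is None:
        cols = list(range(X_all.shape[1]))
    elif all(isinstance(f, str) for f in feature_subset):
        cols = [all_names.index(f) for f in feature_subset]  # type: ignore[arg-type]
    else:
        cols = [int(f) for f in feature_subset]
    sub_names = tuple(all_names[j] for j in cols)
    X = X_all[:, cols]

    if divisions is None:
        divisions = make_divisions(y, R, seed)
    elif len(divisions) < R:
        raise ValueError("fewer divisions provided than R")
    divisions = divisions[:R]

    if not leakage_safe:
        sm = standardize(X, names=sub_names, fitted_on="all")

    rng = np.random.default_rng(seed + 1)
    member_seeds = rng.integers(0, 2**31 - 1, size=R)

    per_division: list[dict[str, float]] = []
    weights: list[np.ndarray] = []
    curves = []
    for r, (learn, test) in enumerate(divisions):
        if leakage_safe:
            sm_r = standardize(X[learn], names=sub_names, fitted_on="learning")
            Xt_learn = sm_r.Xtilde
            Xt_test = apply_standardization(X[test], sm_r.mu, sm_r.sigma)
        else:
            Xt_learn = sm.Xtilde[learn]
            Xt_test = sm.Xtilde[test]
        if method == "ssvm":
            ens = bootstrap_bag(Xt_learn, y[learn], B, int(member_seeds[r]),
                                scale=scale, names=sub_names)
            scores = ens.decision_values(Xt_test)
            w_mean, _ = ens.mean_weights()
        else:
            lam = llr_lambda
            if lam is None:
                lam = select_lambda_cv(Xt_learn, y[learn],
                                       seed=int(member_seeds[r]))
            f = fit_llr(Xt_learn, y[learn], lam)
            scores = f.decision_values(Xt_test)
            w_mean = f.w
        y_pred = np.where(scores >= 0, 1, -1)
        per_division.append(measures(confusion(y[test], y_pred)))
        weights.append(w_mean)
        if collect_roc:
            curves.append(roc_curve(scores, y[test]))

    W = np.stack(weights)
    summary = PerformanceSummary.from_divisions(
        per_division,
        method=method.upper() if method == "llr" else "SSVM",
        subset=sub_names,
        weights_mean=W.mean(axis=0),
        weights_se=W.std(axis=0, ddof=1) / np.sqrt(R) if R > 1
        else np.full(W.shape[1], np.nan),
    )
    if collect_roc:
        summary.roc_curves = curves
    return summary


# ---------------------------------------------------------------------------
# LASSO logistic regression comparator


def _logistic_loss_grad(w: np.ndarray, b: float, X: np.ndarray,
                        y: np.ndarray) -> tuple[float, np.ndarray, float]:
    z = y * (X @ w + b)
    loss = float(np.logaddexp(0.0, -z).sum())
    s = expit(-z)  # = 1 - sigmoid(z)
    g_common = -y * s
    return loss, X.T @ g_common, float(g_common.sum())


def llr_objective(X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float,
                  lam: float) -> float:
    """Sum logistic loss plus lam * ||w||_1 (bias unpenalized)."""
    z = np.asarray(y, float) * (np.asarray(X, float) @ np.asarray(w, float) + b)
    return float(np.logaddexp(0.0, -z).sum() + lam * np.abs(w).sum())


def fit_llr(Xtilde: np.ndarray, y: np.ndarray, lam: float,
            *, tol: float = 1e-8, max_iter: int = 100_000,
            w0: np.ndarray | None = None, b0: float = 0.0,
            names: Sequence[str] | None = None) -> LinearDecisionFunction:
    """L1-penalized logistic regression by FISTA with an unpenalized bias.

    Minimizes sum_i log(1 + exp(-y_i (w·x_i + b))) + lam * ||w||_1 to a
    stationarity tolerance ``tol`` on the (sub)gradient optimality residual.
    Convex, so the returned point is the global minimum.  Raises on
    non-convergence with diagnostics.
    """
    X = np.asarray(Xtilde, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, k = X.shape
    if names is None:
        names = tuple(f"x{j}" for j in range(k))
    # Lipschitz constant of the sum logistic loss over (w, b)
    A = np.column_stack([X, np.ones(n)])
    L = 0.25 * float(np.linalg.norm(A, 2)) ** 2
    step = 1.0 / L

    w = np.zeros(k) if w0 is None else np.asarray(w0, dtype=float).copy()
    b = float(b0)
    zw, zb, t = w.copy(), b, 1.0
    for it in range(max_iter):
        _, gw, gb = _logistic_loss_grad(zw, zb, X, y)
        w_new = zw - step * gw
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step * lam, 0.0)
        b_new = zb - step * gb
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        zw = w_new + ((t - 1.0) / t_new) * (w_new - w)
        zb = b_new + ((t - 1.0) / t_new) * (b_new - b)
        w, b, t = w_new, b_new, t_new
        if it % 10 == 0 or it == max_iter - 1:
            _, gw_c, gb_c = _logistic_loss_grad(w, b, X, y)
            res_w = np.where(
                w != 0.0,
                np.abs(gw_c + lam * np.sign(w)),
                np.maximum(np.abs(gw_c) - lam, 0.0),
            )
            if max(float(res_w.max(initial=0.0)), abs(gb_c)) <= tol:
                return LinearDecisionFunction(w=w, b=b, names=tuple(names))
    _, gw_c, gb_c = _logistic_loss_grad(w, b, X, y)
    raise RuntimeError(
        f"LLR did not converge in {max_iter} iterations "
        f"(grad residual {max(float(np.abs(gw_c).max()), abs(gb_c)):.3e}, "
        f"lam={lam:g}, n={n}, k={k})")


def select_lambda_cv(Xtilde: np.ndarray, y: np.ndarray, *, n_folds: int = 5,
                     n_lambdas: int = 30, seed: int = 0,
                     tol: float = 1e-6, max_iter: int = 5000) -> float:
    """Pick the LLR penalty by K-fold cross-validated deviance.

    The grid is 30 log-spaced points from lam_max (the smallest penalty
    with an all-zero solution, max |X^T y_c|) down by three decades; folds
    are stratified.  Warm starts run down the path.
    """
    X = np.asarray(Xtilde, dtype=float)
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    lam_max = float(np.abs(X.T @ yc).max())
    if lam_max == 0:
        return 0.0
    grid = np.geomspace(lam_max, lam_max * 1e-3, n_lambdas)
    rng = np.random.default_rng(seed)
    folds = np.empty(y.shape[0], dtype=int)
    for cls in (1, -1):
        idx = np.nonzero(y == cls)[0]
        folds[rng.permutation(idx)] = np.arange(idx.size) % n_folds
    dev = np.zeros(n_lambdas)
    for f in range(n_folds):
        tr, va = folds != f, folds == f
        if np.unique(y[tr]).size < 2 or np.unique(y[va]).size < 2:
            continue
        w, b = np.zeros(X.shape[1]), 0.0
        for i, lam in enumerate(grid):
            try:
                fit = fit_llr(X[tr], y[tr], lam, tol=tol, max_iter=max_iter,
                              w0=w, b0=b)
                w, b = fit.w, fit.b
            except RuntimeError:
                warnings.warn(f"CV fit at lambda={lam:g} hit max_iter; "
                              "using last iterate's fold deviance",
                              UserWarning, stacklevel=2)
            z = y[va] * (X[va] @ w + b)
            dev[i] += 2.0 * float(np.logaddexp(0.0, -z).sum())
    return float(grid[int(np.argmin(dev))])
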