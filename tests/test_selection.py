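"""Canonical-correlation subset selection against independent oracles.

The implementation computes the label-vs-subset canonical correlation as a
multiple correlation via the covariance system; the oracles here are (a) an
intercept-included least-squares R² and (b) the two-set CCA generalized
eigenproblem, both computed independently of the package path.
"""

import numpy as np
import pytest
from scipy import linalg

from sepsispanel import (
    best_subsets,
    canonical_correlation,
    forward_selection,
    groupwise_correlations,
    standardize,
)


def ols_rho(X, y):
    """Oracle: sqrt(R²) from an explicit intercept-included LS fit."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return np.sqrt(max(0.0, 1.0 - ss_res / ss_tot))


def eig_rho(X, y):
    """Oracle: largest canonical correlation from the generalized eigenproblem."""
    Xc = X - X.mean(axis=0)
    yc = (y - y.mean())[:, None]
    Cxx = Xc.T @ Xc
    Cyy = yc.T @ yc
    Cxy = Xc.T @ yc
    M = np.linalg.pinv(Cxx) @ Cxy @ np.linalg.pinv(Cyy) @ Cxy.T
    return float(np.sqrt(np.clip(np.max(linalg.eigvals(M).real), 0, 1)))


def test_self_correlation_is_one(rng):
    y = rng.choice([-1.0, 1.0], size=40)
    assert canonical_correlation(y[:, None], y) == pytest.approx(1.0, abs=1e-12)


def test_orthogonal_column_gives_zero(rng):
    y = np.repeat([1.0, -1.0], 20)
    x = rng.normal(size=40)
    yc = y - y.mean()
    x = x - x.mean() - (x - x.mean()) @ yc / (yc @ yc) * yc
    assert canonical_correlation(x[:, None], y) == pytest.approx(0.0, abs=1e-10)


def test_matches_ols_oracle_on_random_instances(rng):
    for _ in range(200):
        k = int(rng.integers(1, 7))
        X = rng.normal(size=(40, k))
        y = rng.choice([-1.0, 1.0], size=40)
        assert canonical_correlation(X, y) == pytest.approx(
            ols_rho(X, y), abs=1e-10)


def test_matches_generalized_eigenproblem_oracle(rng):
    for _ in range(50):
        X = rng.normal(size=(35, int(rng.integers(1, 6))))
        y = rng.choice([-1.0, 1.0], size=35)
        assert canonical_correlation(X, y) == pytest.approx(
            eig_rho(X, y), abs=1e-9)


def test_rank_deficient_submatrix_handled(rng):
    x = rng.normal(size=50)
    X = np.column_stack([x, x, 2 * x])  # rank 1
    y = rng.choice([-1.0, 1.0], size=50)
    rho = canonical_correlation(X, y)
    assert 0.0 <= rho <= 1.0
    assert rho == pytest.approx(abs(np.corrcoef(x, y)[0, 1]), abs=1e-9)


def test_full_subset_is_multiple_correlation(rng):
    X = rng.normal(size=(60, 4))
    y = rng.choice([-1.0, 1.0], size=60)
    path = best_subsets(X, y)
    assert path.best[-1].indices == (0, 1, 2, 3)
    assert path.best[-1].rho == pytest.approx(ols_rho(X, y), abs=1e-10)


def test_rho_nondecreasing_in_k(rng):
    for _ in range(10):
        X = rng.normal(size=(80, 8))
        y = rng.choice([-1.0, 1.0], size=80)
        rhos = [sc.rho for sc in best_subsets(X, y).best]
        assert np.all(np.diff(rhos) >= -1e-12)


def test_best_subsets_agree_with_brute_force_oracle(rng):
    """Winner per k equals an independent argmax over OLS-R² of all subsets."""
    from itertools import combinations

    X = rng.normal(size=(50, 6))
    y = rng.choice([-1.0, 1.0], size=50)
    path = best_subsets(X, y)
    for sc in path.best:
        best = max(combinations(range(6), sc.k),
                   key=lambda idx: ols_rho(X[:, idx], y) - 1e-15 * sum(idx))
        assert ols_rho(X[:, best], y) == pytest.approx(sc.rho, abs=1e-10)


def test_enter_leave_are_exact_set_differences(planted_standardized):
    sm, ds, _ = planted_standardized
    path = best_subsets(sm.Xtilde, ds.y, names=ds.names)
    prev = set()
    for i, sc in enumerate(path.best):
        cur = {ds.names[j] for j in sc.indices}
        assert set(path.enter[i]) == cur - prev
        assert set(path.leave[i]) == prev - cur
        prev = cur


def test_planted_panel_is_best_five_subset(planted_standardized):
    sm, ds, truth = planted_standardized
    path = best_subsets(sm.Xtilde, ds.y, k_range=[5], names=ds.names)
    found = sorted(ds.names[j] for j in path.best[0].indices)
    assert found == sorted(truth["informative_names"])


def test_enumeration_guard():
    X = np.zeros((10, 30))
    with pytest.raises(ValueError, match="guard"):
        best_subsets(X, np.ones(10))


def test_forward_selection_finds_informative_column_first(rng):
    X = rng.normal(size=(200, 6))
    y = np.sign(X[:, 3] + 0.3 * rng.normal(size=200))
    order = forward_selection(X, y)
    assert order[0] == "x3"


def test_forward_selection_orthonormal_equals_univariate_ranking(rng):
    """On an orthogonal design FS reduces to ranking by |corr(x_j, y)|."""
    M = rng.normal(size=(64, 5))
    Q, _ = np.linalg.qr(M - M.mean(axis=0))
    y = rng.choice([-1.0, 1.0], size=64)
    order = forward_selection(Q, y)
    yc = y - y.mean()
    ranking = np.argsort(-np.abs(Q.T @ yc))
    assert order == tuple(f"x{j}" for j in ranking)


def test_suppressor_design_separates_greedy_from_exhaustive():
    """A jointly informative pair beats the greedy path: FS ≠ best-2 subset."""
    rng = np.random.default_rng(5)
    n = 400
    z = rng.normal(size=n)
    x2 = rng.normal(size=n)
    x1 = z + x2          # x1 alone is noisy; x1 − x2 recovers z
    x3 = z + 0.8 * rng.normal(size=n)  # decent on its own
    X = np.column_stack([x1, x2, x3])
    y = np.sign(z)
    path = best_subsets(X, y)
    best2 = set(path.best[1].indices)
    fs2 = {int(name[1:]) for name in path.fs_order[:2]}
    assert best2 == {0, 1}
    assert fs2 != best2


def test_groupwise_correlations(planted_dataset):
    ds, _ = planted_dataset
    pos, neg, meta = groupwise_correlations(ds.X, ds.y, ds.names)
    for M in (pos, neg):
        np.testing.assert_allclose(np.diag(M), 1.0)
        np.testing.assert_allclose(M, M.T)
    assert len(meta["order_by_abs_label_corr"]) == len(ds.names)


def test_groupwise_identical_columns_give_unit_correlation(rng):
    x = rng.normal(size=60)
    X = np.column_stack([x, x, rng.normal(size=60)])
    y = np.repeat([1.0, -1.0], 30)
    pos, neg, _ = groupwise_correlations(X, y)
    assert pos.iloc[0, 1] == pytest.approx(1.0)
    assert neg.iloc[0, 1] == pytest.approx(1.0)


def test_groupwise_constant_column_flagged(rng):
    X = np.column_stack([np.ones(40), rng.normal(size=40)])
    y = np.repeat([1.0, -1.0], 20)
    pos, neg, meta = groupwise_correlations(X, y)
    assert "x0" in meta["constant_columns"]["septic"]
    assert pos.iloc[0, 1] == 0.0


def test_sample_correlation_ordering_survives_generation(planted_dataset):
    """In a generated cohort the Bands–CD64 vs Bands–Plt ordering from the
    target correlation shows up in both group sample matrices."""
    from sepsispanel import default_cohort_spec, generate_cohort, make_labels

    df = generate_cohort(default_cohort_spec(10_000, 10_000, seed=23))
    ds = make_labels(df)
    pos, neg, _ = groupwise_correlations(ds.X, ds.y, ds.names)
    for M in (pos, neg):
        assert abs(M.loc["Bands", "CD64"]) > abs(M.loc["Bands", "Plt"])
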