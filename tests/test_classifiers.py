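"""1-norm SSVM linear program, bagging and the LASSO-logistic comparator.

The independent SSVM oracle is a *different* LP parameterization (free w
with auxiliary t >= |w| constraints, dense matrices, default HiGHS) so that
agreement checks objective values across two formulations, not one code
path against itself.
"""

import numpy as np
import pytest
from scipy.optimize import linprog

from sepsispanel import (
    EnsembleClassifier,
    LinearDecisionFunction,
    SSVMProblem,
    balanced_costs,
    bootstrap_bag,
    bootstrap_indices,
    fit_llr,
    fit_ssvm,
    make_divisions,
    make_labels,
    planted_panel_cohort,
    predict,
    repeated_evaluation,
    select_lambda_cv,
)
from sepsispanel.classifiers import llr_objective, ssvm_objective


def oracle_ssvm_objective(X, y, c_pos, c_neg):
    """Alternative LP: variables (w, t, b, xi); min sum t + cost.xi,
    t >= w, t >= -w, margin constraints.  Dense, default HiGHS."""
    n, k = X.shape
    cost = np.where(y == 1, c_pos, c_neg)
    # var order: w(k) t(k) b xi(n)
    c = np.concatenate([np.zeros(k), np.ones(k), [0.0], cost])
    A1 = np.hstack([np.eye(k), -np.eye(k), np.zeros((k, 1 + n))])   # w - t <= 0
    A2 = np.hstack([-np.eye(k), -np.eye(k), np.zeros((k, 1 + n))])  # -w - t <= 0
    A3 = np.hstack([-(y[:, None] * X), np.zeros((n, k)), -y[:, None],
                    -np.eye(n)])                                    # margin
    A = np.vstack([A1, A2, A3])
    b_ub = np.concatenate([np.zeros(2 * k), -np.ones(n)])
    bounds = [(None, None)] * k + [(0, None)] * k + [(None, None)] \
        + [(0, None)] * n
    res = linprog(c, A_ub=A, b_ub=b_ub, bounds=bounds, method="highs")
    assert res.success
    return res.fun


TOY_X = np.array([[-1.0], [1.0]])
TOY_Y = np.array([-1.0, 1.0])


def test_separable_toy_has_unit_weight_zero_bias():
    """The minimum-‖w‖₁ separator of {(-1,-1),(+1,+1)} is w=1, b=0."""
    f, xi = fit_ssvm(SSVMProblem(TOY_X, TOY_Y, 1000.0, 1000.0))
    assert f.w[0] == pytest.approx(1.0, abs=1e-9)
    assert f.b == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(xi.xi, 0.0, atol=1e-9)


def test_pure_noise_feature_gets_zero_weight(rng):
    """Appending noise to a separable 1-D problem leaves its weight at 0."""
    n = 40
    y = np.repeat([1.0, -1.0], n // 2)
    x = y + 0.1 * rng.normal(size=n)
    noise = rng.normal(size=n)
    X = np.column_stack([x, noise])
    f, _ = fit_ssvm(SSVMProblem(X, y, 100.0, 100.0))
    assert f.w[1] == pytest.approx(0.0, abs=1e-9)
    assert f.w[0] > 0
    # and the two-formulation objectives agree
    obj = ssvm_objective(SSVMProblem(X, y, 100.0, 100.0), f.w, f.b)
    assert obj == pytest.approx(oracle_ssvm_objective(X, y, 100.0, 100.0),
                                abs=1e-8)


def test_objective_matches_independent_lp_on_random_instances(rng):
    for _ in range(50):
        X = rng.normal(size=(30, 5))
        y = rng.choice([-1.0, 1.0], size=30)
        if len(np.unique(y)) < 2:
            continue
        c_pos, c_neg = balanced_costs(int((y == 1).sum()),
                                      int((y == -1).sum()),
                                      scale=float(rng.uniform(0.2, 3.0)))
        prob = SSVMProblem(X, y, c_pos, c_neg)
        f, xi = fit_ssvm(prob)
        ours = ssvm_objective(prob, f.w, f.b, xi.xi)
        assert ours == pytest.approx(
            oracle_ssvm_objective(X, y, c_pos, c_neg), abs=1e-8)


def test_slack_consistency(rng):
    """ξ equals the hinge violation at the optimum, and replacing it with
    that minimum leaves the objective unchanged."""
    X = rng.normal(size=(40, 4))
    y = rng.choice([-1.0, 1.0], size=40)
    prob = SSVMProblem(X, y, 2.0, 1.0)
    f, xi = fit_ssvm(prob)
    hinge = np.maximum(0.0, 1.0 - y * (X @ f.w + f.b))
    assert np.all(xi.xi >= hinge - 1e-8)
    assert ssvm_objective(prob, f.w, f.b, xi.xi) == pytest.approx(
        ssvm_objective(prob, f.w, f.b), abs=1e-8)


def test_returned_solution_beats_feasible_constructions(rng):
    """LP optimality: no feasible (w, b) built by the suite scores lower."""
    X = rng.normal(size=(30, 3))
    y = rng.choice([-1.0, 1.0], size=30)
    prob = SSVMProblem(X, y, 1.5, 1.5)
    f, _ = fit_ssvm(prob)
    opt = ssvm_objective(prob, f.w, f.b)
    for _ in range(200):
        w = rng.normal(size=3) * rng.choice([0.1, 1.0, 5.0])
        b = float(rng.normal())
        assert opt <= ssvm_objective(prob, w, b) + 1e-8


def test_balanced_costs_identity():
    # exact IEEE equality where the arithmetic is representable
    for n_pos, n_neg, scale in [(30, 60, 1.0), (1, 99, 2.0), (7, 7, 0.25),
                                (25, 75, 1.0), (128, 64, 0.5)]:
        c_pos, c_neg = balanced_costs(n_pos, n_neg, scale)
        assert c_pos * n_pos == c_neg * n_neg
    # arbitrary counts agree to rounding error
    rng = np.random.default_rng(8)
    for _ in range(100):
        n_pos, n_neg = (int(v) for v in rng.integers(1, 500, 2))
        scale = float(rng.uniform(0.1, 5))
        c_pos, c_neg = balanced_costs(n_pos, n_neg, scale)
        assert c_pos * n_pos == pytest.approx(c_neg * n_neg, rel=1e-15)
    assert balanced_costs(30, 60, 1.0) == (1.5, 0.75)
    assert balanced_costs(10, 10, 2.0) == (2.0, 2.0)


def test_scale_invariance_on_separable_data(rng):
    n = 60
    y = np.repeat([1.0, -1.0], n // 2)
    X = np.column_stack([y + 0.05 * rng.normal(size=n),
                         rng.normal(size=n)])
    preds = []
    for scale in (0.5, 5.0):  # 10x change
        c_pos, c_neg = balanced_costs(n // 2, n // 2, scale)
        f, _ = fit_ssvm(SSVMProblem(X, y, c_pos, c_neg))
        preds.append(np.sign(X @ f.w + f.b))
    np.testing.assert_array_equal(preds[0], preds[1])


def test_sparsity_monotone_in_scale(rng):
    """Weakening the slack costs never adds nonzero weights (5-point grid)."""
    X = rng.normal(size=(80, 6))
    beta = np.array([2.0, -1.5, 1.0, 0.0, 0.0, 0.0])
    y = np.sign(X @ beta + rng.normal(size=80))
    nnz = []
    for scale in (3.0, 1.0, 0.3, 0.1, 0.03):
        c_pos, c_neg = balanced_costs(int((y == 1).sum()),
                                      int((y == -1).sum()), scale)
        f, _ = fit_ssvm(SSVMProblem(X, y, c_pos, c_neg))
        nnz.append(int((np.abs(f.w) > 1e-9).sum()))
    assert np.all(np.diff(nnz) <= 0)


def test_bootstrap_unique_fraction_matches_closed_form(rng):
    """Mean unique fraction ≈ 1 − (1 − 1/n)^n at n=200 over 1000 resamples."""
    n = 200
    fracs = [np.unique(bootstrap_indices(rng, n)).size / n
             for _ in range(1000)]
    expected = 1.0 - (1.0 - 1.0 / n) ** n
    assert abs(np.mean(fracs) - expected) < 0.02


def test_bag_with_identity_resampler_reduces_to_single_fit(rng):
    X = rng.normal(size=(50, 3))
    y = np.repeat([1.0, -1.0], 25)
    ens = bootstrap_bag(X, y, B=1, seed=0,
                        resampler=lambda rng, n: np.arange(n))
    c_pos, c_neg = balanced_costs(25, 25, 1.0)
    f, _ = fit_ssvm(SSVMProblem(X, y, c_pos, c_neg))
    np.testing.assert_allclose(ens.members[0].w, f.w, atol=1e-9)
    assert ens.members[0].b == pytest.approx(f.b, abs=1e-9)


def test_bag_determinism(rng):
    X = rng.normal(size=(60, 4))
    y = np.repeat([1.0, -1.0], 30)
    a = bootstrap_bag(X, y, B=5, seed=42)
    b = bootstrap_bag(X, y, B=5, seed=42)
    for ma, mb in zip(a.members, b.members):
        np.testing.assert_array_equal(ma.w, mb.w)
        assert ma.b == mb.b


def test_bag_requires_both_classes(rng):
    X = rng.normal(size=(10, 2))
    with pytest.raises(ValueError, match="both classes"):
        bootstrap_bag(X, np.ones(10), B=2, seed=0)


def test_ensemble_of_identical_members_equals_member_score(rng):
    f = LinearDecisionFunction(w=np.array([1.0, -2.0]), b=0.5,
                               names=("a", "b"))
    ens = EnsembleClassifier(members=[f, f, f], names=("a", "b"))
    X = rng.normal(size=(20, 2))
    scores, _ = predict(ens, X)
    np.testing.assert_allclose(scores, X @ f.w + f.b)


def test_zero_score_is_diagnosed_positive():
    f = LinearDecisionFunction(w=np.array([1.0]), b=0.0, names=("a",))
    ens = EnsembleClassifier(members=[f], names=("a",))
    _, labels = predict(ens, np.array([[0.0]]))
    assert labels[0] == 1


def test_negating_members_negates_scores(rng):
    X = rng.normal(size=(15, 2))
    f = LinearDecisionFunction(w=np.array([0.7, -1.1]), b=0.3,
                               names=("a", "b"))
    g = LinearDecisionFunction(w=-f.w, b=-f.b, names=("a", "b"))
    s1, _ = predict(EnsembleClassifier(members=[f], names=("a", "b")), X)
    s2, _ = predict(EnsembleClassifier(members=[g], names=("a", "b")), X)
    np.testing.assert_allclose(s2, -s1)


def test_ensemble_score_variance_shrinks_with_B(rng):
    """Across independent bags, the ensemble score varies less at larger B."""
    X = rng.normal(size=(80, 3))
    beta = np.array([1.5, -1.0, 0.0])
    y = np.sign(X @ beta + 0.5 * rng.normal(size=80))
    x0 = X[:5]
    scores = {B: [bootstrap_bag(X, y, B=B, seed=s).decision_values(x0)
                  for s in range(12)] for B in (10, 100)}
    var10 = np.stack(scores[10]).var(axis=0).mean()
    var100 = np.stack(scores[100]).var(axis=0).mean()
    assert var100 < var10


def test_divisions_are_stratified_and_shared(rng):
    y = np.repeat([1.0, -1.0], [40, 80])
    divs = make_divisions(y, R=6, seed=1)
    divs2 = make_divisions(y, R=6, seed=1)
    for (l1, t1), (l2, t2) in zip(divs, divs2):
        np.testing.assert_array_equal(t1, t2)
        assert len(np.intersect1d(l1, t1)) == 0
        assert len(l1) + len(t1) == 120
        # stratified thirds per class
        assert (y[t1] == 1).sum() == pytest.approx(13, abs=1)
        assert (y[t1] == -1).sum() == pytest.approx(27, abs=1)


def test_repeated_evaluation_reproducible(planted_dataset):
    ds, _ = planted_dataset
    kwargs = dict(feature_subset=("Bands", "CD64"), R=1, B=1, seed=9)
    a = repeated_evaluation(ds, **kwargs)
    b = repeated_evaluation(ds, **kwargs)
    assert a.mean == b.mean and a.sd == b.sd
    np.testing.assert_array_equal(a.weights_mean, b.weights_mean)


def test_separable_planted_data_near_perfect_accuracy():
    table, truth = planted_panel_cohort(["Bands", "CD64"], 6.0, 150, 150,
                                        seed=31)
    ds = make_labels(table)
    s = repeated_evaluation(ds, feature_subset=truth["informative_names"],
                            R=10, B=25, seed=5)
    assert s.mean["ACC"] >= 0.99


def test_label_permutation_gives_chance_accuracy():
    table, _ = planted_panel_cohort(["Bands"], 1.5, 300, 300, seed=37)
    ds = make_labels(table)
    rng = np.random.default_rng(0)
    ds.y = ds.y[rng.permutation(ds.n)]
    ds.group = np.where(ds.y == 1, 2, 3)  # keep invariant satisfied
    s = repeated_evaluation(ds, R=10, B=10, seed=6)
    assert abs(s.mean["ACC"] - 0.5) <= 3 * s.sd["ACC"] + 1e-9


# --- LASSO logistic regression -------------------------------------------


def test_llr_full_shrinkage_at_large_lambda(rng):
    X = rng.normal(size=(100, 4))
    y = np.sign(X[:, 0] + rng.normal(size=100))
    yc = y - y.mean()
    lam = 2.0 * float(np.abs(X.T @ yc).max())
    f = fit_llr(X, y, lam)
    np.testing.assert_allclose(f.w, 0.0, atol=1e-10)


def test_llr_unpenalized_matches_sklearn_mle(rng):
    sklearn_lm = pytest.importorskip("sklearn.linear_model")
    X = rng.normal(size=(120, 3))
    y = np.sign(X @ np.array([1.0, -0.5, 0.2]) + 1.5 * rng.normal(size=120))
    f = fit_llr(X, y, 0.0, tol=1e-10)
    ref = sklearn_lm.LogisticRegression(penalty=None, tol=1e-12,
                                        max_iter=20000).fit(X, y)
    np.testing.assert_allclose(f.w, ref.coef_[0], atol=1e-6)
    assert f.b == pytest.approx(float(ref.intercept_[0]), abs=1e-6)


def test_llr_solution_is_global_minimum(rng):
    """Convexity: the returned point beats 1000 random perturbations."""
    X = rng.normal(size=(80, 4))
    y = np.sign(X[:, 0] - X[:, 1] + rng.normal(size=80))
    lam = 3.0
    f = fit_llr(X, y, lam)
    opt = llr_objective(X, y, f.w, f.b, lam)
    for _ in range(1000):
        dw = rng.normal(size=4) * rng.choice([1e-3, 1e-1, 1.0])
        db = float(rng.normal() * 1e-1)
        assert opt <= llr_objective(X, y, f.w + dw, f.b + db, lam) + 1e-10


def test_llr_nonconvergence_raises(rng):
    X = rng.normal(size=(50, 2))
    y = np.sign(X[:, 0] + 0.3 * rng.normal(size=50))
    with pytest.raises(RuntimeError, match="converge"):
        fit_llr(X, y, 0.5, max_iter=2)


def test_lambda_cv_returns_grid_member(rng):
    X = rng.normal(size=(90, 3))
    y = np.sign(X[:, 0] + rng.normal(size=90))
    lam = select_lambda_cv(X, y, seed=3)
    assert lam > 0
    f = fit_llr(X, y, lam)
    assert np.abs(f.w).max() > 0  # CV does not pick total shrinkage here
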