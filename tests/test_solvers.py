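"""Sparse solver correctness: proximal operators, lambda_max, oracle
equivalence (sklearn coordinate descent for l1; dense grid for group
penalties), reduction identities, and convergence behavior."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso

from hyperfc.solvers import (
    PenaltySpec,
    RegressionProblem,
    SolverConfig,
    absolute_lambdas,
    compute_lambda_max,
    group_shrink,
    objective_value,
    soft_threshold,
    solve_sparse_regression,
)

from conftest import random_problem
import oracles


# ---------------------------------------------------------------- prox ops
@pytest.mark.parametrize(
    "z,t,expected",
    [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (-2.5, 1.0, -1.5), (0.0, 0.0, 0.0)],
)
def test_soft_threshold(z, t, expected):
    assert soft_threshold(z, t) == pytest.approx(expected)


@pytest.mark.parametrize(
    "v,t,expected",
    [
        ((3.0, 4.0), 0.0, (3.0, 4.0)),
        ((3.0, 4.0), 5.0, (0.0, 0.0)),
        ((3.0, 4.0), 2.5, (1.5, 2.0)),
        ((0.0, 0.0), 1.0, (0.0, 0.0)),
    ],
)
def test_group_shrink(v, t, expected):
    assert group_shrink(np.array(v), t) == pytest.approx(np.array(expected))


def test_prox_operators_reject_negative_threshold():
    with pytest.raises(ValueError):
        soft_threshold(1.0, -0.1)
    with pytest.raises(ValueError):
        group_shrink(np.ones(2), -0.1)


# ---------------------------------------------------------------- objective
def _fixed_problem():
    design = np.array(
        [[0.0, 1.0, 0.5, -1.0], [0.0, -1.0, 2.0, 0.5], [0.0, 0.5, -1.0, 1.0]]
    )
    return RegressionProblem(
        response=np.array([1.0, 2.0, -1.0]), design=design, centroid_index=0
    )


def test_objective_zero_coefficients_is_half_squared_norm():
    p = _fixed_problem()
    spec = PenaltySpec(kind="lasso", ratio_l1=0.5)
    val = objective_value(p, np.zeros(4), spec, (1.0, 0.0))
    assert val == pytest.approx(0.5 * np.sum(p.response**2))


def test_objective_lasso_penalty_by_hand():
    p = _fixed_problem()
    spec = PenaltySpec(kind="lasso", ratio_l1=0.5)
    a = np.array([0.0, 1.0, -1.0, 0.0])
    loss = 0.5 * np.sum((p.response - p.design @ a) ** 2)
    assert objective_value(p, a, spec, (1.0, 0.0)) == pytest.approx(loss + 2.0)


def test_objective_sglasso_penalty_by_hand():
    # groups {1,2},{3}: coefficients (3,4|0) -> l1 part 7, group part 5
    p = _fixed_problem()
    spec = PenaltySpec(
        kind="sglasso",
        ratio_l1=0.5,
        ratio_group=0.5,
        partition=[np.array([1, 2]), np.array([3])],
    )
    a = np.array([0.0, 3.0, 4.0, 0.0])
    loss = 0.5 * np.sum((p.response - p.design @ a) ** 2)
    assert objective_value(p, a, spec, (1.0, 1.0)) == pytest.approx(loss + 7.0 + 5.0)


# ---------------------------------------------------------------- lambda_max
def test_lambda_max_orthogonal_response_is_zero():
    design = np.zeros((4, 3))
    design[:, 1] = [1.0, -1.0, 1.0, -1.0]
    p = RegressionProblem(
        response=np.array([1.0, 1.0, -1.0, -1.0]), design=design, centroid_index=0
    )
    spec = PenaltySpec(kind="lasso", ratio_l1=0.5)
    assert compute_lambda_max(p, spec) == pytest.approx(0.0)


def test_lambda_max_matches_gradient_magnitude():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(20)
    x /= np.linalg.norm(x)
    design = np.zeros((20, 2))
    design[:, 1] = x
    p = RegressionProblem(response=x, design=design, centroid_index=0)
    spec = PenaltySpec(kind="lasso", ratio_l1=0.5)
    assert compute_lambda_max(p, spec) == pytest.approx(abs(x @ x))


def test_lambda_max_zero_variance_response_errors():
    design = np.zeros((5, 2))
    design[:, 1] = 1.0
    p = RegressionProblem(
        response=np.zeros(5), design=design, centroid_index=0
    )
    with pytest.raises(ValueError, match="zero variance"):
        compute_lambda_max(p, PenaltySpec(kind="lasso", ratio_l1=0.5))


def _specs_for(problem, groups):
    return {
        "lasso": PenaltySpec(kind="lasso", ratio_l1=1.0),
        "glasso": PenaltySpec(kind="glasso", ratio_group=1.0, partition=groups),
        "sglasso": PenaltySpec(
            kind="sglasso", ratio_l1=1.0, ratio_group=0.4, partition=groups
        ),
    }


def test_ratio_one_returns_all_zeros():
    """At the lambda_max ratio the solution is identically zero, for every
    penalty kind."""
    rng = np.random.default_rng(1)
    p = random_problem(rng, T=20, M=6)
    groups = [np.array([0, 1, 2]), np.array([3, 4, 5])]
    for spec in _specs_for(p, groups).values():
        sol = solve_sparse_regression(p, spec)
        assert sol.support.size == 0
        assert sol.converged


# ---------------------------------------------------------------- solve
def test_solution_beats_dense_grid_oracle():
    """Solver objective <= objective at every point of a dense coefficient
    grid, for all three penalties (8 samples x 4 columns, step 0.1)."""
    rng = np.random.default_rng(2)
    data = rng.standard_normal((4, 8))
    data[1] = 0.8 * data[0] + 0.2 * data[1]
    p = RegressionProblem.from_timeseries(data, centroid_index=0)
    groups = [np.array([0, 1]), np.array([2, 3])]

    grid_1d = np.arange(-2.0, 2.0 + 1e-9, 0.1)
    mesh = np.stack(np.meshgrid(*([grid_1d] * 3), indexing="ij"), axis=-1).reshape(-1, 3)
    coeffs = np.zeros((mesh.shape[0], 4))
    coeffs[:, 1:] = mesh  # centroid coefficient fixed at zero

    for kind, spec in _specs_for(p, groups).items():
        spec = PenaltySpec(
            kind=spec.kind,
            ratio_l1={"lasso": 0.3, "glasso": None, "sglasso": 0.3}[kind],
            ratio_group={"lasso": None, "glasso": 0.3, "sglasso": 0.4}[kind],
            partition=spec.partition,
        )
        lam1, lam2 = absolute_lambdas(p, spec)
        sol = solve_sparse_regression(p, spec)
        resid = p.response[:, None] - p.design @ coeffs.T
        losses = 0.5 * np.sum(resid**2, axis=0)
        pens = lam1 * np.abs(coeffs).sum(axis=1)
        if lam2 > 0:
            pens = pens + lam2 * (
                np.linalg.norm(coeffs[:, :2], axis=1)
                + np.linalg.norm(coeffs[:, 2:], axis=1)
            )
        grid_best = float(np.min(losses + pens))
        assert sol.objective <= grid_best + 1e-6


def test_lasso_matches_sklearn_coordinate_descent():
    """Our FISTA lasso equals sklearn's coordinate-descent Lasso: objective
    (1/2)||y-Xw||^2 + lam*||w||_1 corresponds to alpha = lam / n_samples."""
    rng = np.random.default_rng(3)
    for _ in range(5):
        p = random_problem(rng, T=30, M=8)
        spec = PenaltySpec(kind="lasso", ratio_l1=0.3)
        lam, _ = absolute_lambdas(p, spec)
        ours = solve_sparse_regression(p, spec, SolverConfig(tolerance=1e-12))
        ref = Lasso(
            alpha=lam / p.n_timepoints, fit_intercept=False, tol=1e-12, max_iter=100000
        ).fit(p.design, p.response)
        assert ours.values == pytest.approx(ref.coef_, abs=1e-4)
        our_obj = ours.objective
        ref_obj = oracles.sgl_objective(p.design, p.response, ref.coef_, lam, 0.0, [])
        assert our_obj <= ref_obj + 1e-6


def test_sglasso_reduction_to_lasso_and_glasso():
    """sglasso with the group ratio at 0 reproduces lasso; with the l1 ratio
    at 0 it reproduces glasso (coefficients within 1e-6)."""
    rng = np.random.default_rng(4)
    cfg = SolverConfig(tolerance=1e-13, max_iterations=20000)
    for _ in range(3):
        p = random_problem(rng, T=25, M=6)
        groups = [np.array([0, 1, 2]), np.array([3, 4, 5])]
        lasso = solve_sparse_regression(p, PenaltySpec(kind="lasso", ratio_l1=0.3), cfg)
        sgl_l1 = solve_sparse_regression(
            p,
            PenaltySpec(kind="sglasso", ratio_l1=0.3, ratio_group=0.0, partition=groups),
            cfg,
        )
        assert sgl_l1.values == pytest.approx(lasso.values, abs=1e-6)
        glasso = solve_sparse_regression(
            p, PenaltySpec(kind="glasso", ratio_group=0.3, partition=groups), cfg
        )
        sgl_g = solve_sparse_regression(
            p,
            PenaltySpec(kind="sglasso", ratio_l1=0.0, ratio_group=0.3, partition=groups),
            cfg,
        )
        assert sgl_g.values == pytest.approx(glasso.values, abs=1e-6)


def test_centroid_coefficient_always_zero():
    rng = np.random.default_rng(5)
    for m in range(3):
        data = rng.standard_normal((5, 15))
        p = RegressionProblem.from_timeseries(data, centroid_index=m)
        sol = solve_sparse_regression(p, PenaltySpec(kind="lasso", ratio_l1=0.1))
        assert sol.values[m] == 0.0
        assert m not in sol.support


def test_nan_data_rejected():
    design = np.zeros((5, 3))
    design[:, 1] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        RegressionProblem(response=np.ones(5), design=design, centroid_index=0)


def test_penalty_spec_validation():
    with pytest.raises(ValueError):
        PenaltySpec(kind="lasso", ratio_l1=0.5, ratio_group=0.5)
    with pytest.raises(ValueError):
        PenaltySpec(kind="glasso", ratio_group=0.5)  # no partition
    with pytest.raises(ValueError):
        PenaltySpec(kind="sglasso", ratio_l1=0.5, partition=[np.array([0])])
    with pytest.raises(ValueError):
        PenaltySpec(kind="lasso", ratio_l1=1.5)


def test_partition_must_cover_columns():
    rng = np.random.default_rng(6)
    p = random_problem(rng, T=12, M=5)
    spec = PenaltySpec(
        kind="glasso", ratio_group=0.5, partition=[np.array([1, 2])]
    )
    with pytest.raises(ValueError, match="partition"):
        solve_sparse_regression(p, spec)


def test_standardization_zscores_and_zeroes_centroid():
    rng = np.random.default_rng(7)
    data = rng.standard_normal((4, 50)) * 5 + 3
    p = RegressionProblem.from_timeseries(data, centroid_index=2)
    assert np.all(p.design[:, 2] == 0)
    keep = [0, 1, 3]
    assert p.design[:, keep].mean(axis=0) == pytest.approx(np.zeros(3), abs=1e-12)
    assert p.design[:, keep].std(axis=0) == pytest.approx(np.ones(3))
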