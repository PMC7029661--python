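"""Penalized least-squares solvers that define hyperedges.

For a centroid ROI m the response is that ROI's time series and the design
matrix holds every ROI's series as a column with the centroid column zeroed,
so the fit expresses one region as a sparse linear combination of the others.
Three penalties are supported on the coefficient vector alpha:

* ``lasso``    : lambda * ||alpha||_1
* ``glasso``   : beta * sum_g ||alpha_g||_2           (non-overlapping groups)
* ``sglasso``  : lambda1 * ||alpha||_1 + lambda2 * sum_g ||alpha_g||_2

The internal loss is (1/2) ||x - A alpha||_2^2, the differentiable convention
under which the closed-form lambda_max expressions hold (lambda_max is the
smallest penalty level whose solution is identically zero).  User-facing
regularization strengths are ratios in [0, 1] of lambda_max, so a ratio of
1.0 always returns the empty model; for sglasso each of the two ratios scales
its own lambda_max independently.  Group norms are unweighted (no sqrt of
group size factor).

Optimization is FISTA (accelerated proximal gradient) with adaptive restart
on objective increase; the proximal operator of the mixed penalty is soft
thresholding followed by per-group shrinkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RegressionProblem",
    "PenaltySpec",
    "SolverConfig",
    "CoefficientVector",
    "soft_threshold",
    "group_shrink",
    "objective_value",
    "compute_lambda_max",
    "solve_sparse_regression",
]

PENALTY_KINDS = ("lasso", "glasso", "sglasso")


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class RegressionProblem:
    """One centroid ROI's regression: response x, design A with the centroid
    column identically zero.  Indices are 0-based."""

    response: np.ndarray
    design: np.ndarray
    centroid_index: int

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float).ravel()
        self.design = np.asarray(self.design, dtype=float)
        T, M = self.design.shape
        if self.response.shape[0] != T:
            raise ValueError("response length must match design rows")
        if T < 2 or M < 2:
            raise ValueError("need at least 2 timepoints and 2 ROIs")
        if not 0 <= self.centroid_index < M:
            raise ValueError("centroid_index out of range")
        if not (np.all(np.isfinite(self.response)) and np.all(np.isfinite(self.design))):
            raise ValueError("NaN or inf in regression data")
        if np.any(self.design[:, self.centroid_index] != 0):
            raise ValueError("design column at centroid_index must be all zeros")

    @property
    def n_timepoints(self) -> int:
        return self.design.shape[0]

    @property
    def n_rois(self) -> int:
        return self.design.shape[1]

    @classmethod
    def from_timeseries(
        cls, data: np.ndarray, centroid_index: int, standardize: bool = True
    ) -> "RegressionProblem":
        """Build the problem for one centroid from an ROI x timepoint matrix.

        Rows are z-scored (the standard scale on which penalty ratios are
        comparable across ROIs) unless ``standardize`` is False, in which
        case rows are only mean-centered.
        """
        data = np.asarray(data, dtype=float)
        sd = data.std(axis=1, ddof=0)
        if np.any(sd == 0):
            bad = int(np.flatnonzero(sd == 0)[0])
            raise ValueError(f"ROI {bad} has zero variance")
        centered = data - data.mean(axis=1, keepdims=True)
        Z = (centered / sd[:, None]).T if standardize else centered.T
        response = Z[:, centroid_index].copy()
        design = Z.copy()
        design[:, centroid_index] = 0.0
        return cls(response=response, design=design, centroid_index=centroid_index)


@dataclass
class PenaltySpec:
    """Penalty kind plus regularization ratios (fractions of lambda_max).

    ``lasso`` uses ``ratio_l1`` only; ``glasso`` uses ``ratio_group`` only
    (its single regularization parameter is the group-norm weight beta);
    ``sglasso`` uses both.  ``partition`` maps each group to the ROI/column
    indices it contains and is required whenever a group norm is present.
    """

    kind: str
    ratio_l1: float | None = None
    ratio_group: float | None = None
    partition: Sequence[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.kind not in PENALTY_KINDS:
            raise ValueError(f"kind must be one of {PENALTY_KINDS}")
        if self.kind == "lasso":
            if self.ratio_group is not None:
                raise ValueError("lasso forbids ratio_group")
            if self.ratio_l1 is None:
                raise ValueError("lasso requires ratio_l1")
        elif self.kind == "glasso":
            if self.ratio_l1 is not None:
                raise ValueError("glasso takes its single ratio in ratio_group")
            if self.ratio_group is None:
                raise ValueError("glasso requires ratio_group")
        else:
            if self.ratio_l1 is None or self.ratio_group is None:
                raise ValueError("sglasso requires ratio_l1 and ratio_group")
        for name, r in (("ratio_l1", self.ratio_l1), ("ratio_group", self.ratio_group)):
            if r is not None and not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {r}")
        if self.kind != "lasso":
            if self.partition is None:
                raise ValueError(f"{self.kind} requires a partition")
            self.partition = [np.asarray(g, dtype=int) for g in self.partition]

    def validate_partition(self, n_rois: int, centroid_index: int) -> None:
        """Partition must cover every column exactly once (the centroid's zero
        column may stay inside its group; it never contributes)."""
        if self.partition is None:
            return
        seen = np.concatenate([g for g in self.partition]) if self.partition else np.array([], int)
        counts = np.bincount(seen, minlength=n_rois)
        missing = np.flatnonzero(counts == 0)
        missing = missing[missing != centroid_index]
        if missing.size or np.any(counts > 1):
            raise ValueError("partition must cover each non-centroid index exactly once")


@dataclass
class SolverConfig:
    max_iterations: int = 5000
    tolerance: float = 1e-7
    zero_threshold: float = 1e-8

    def __post_init__(self) -> None:
        if self.max_iterations <= 0 or self.tolerance <= 0 or self.zero_threshold <= 0:
            raise ValueError("all solver config values must be positive")


@dataclass
class CoefficientVector:
    """Solution of one sparse regression; support defines a hyperedge."""

    values: np.ndarray
    centroid_index: int
    converged: bool = True
    n_iterations: int = 0
    objective: float = np.nan

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values[self.centroid_index] != 0.0:
            raise ValueError("centroid coefficient must be exactly zero")

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.values)


def soft_threshold(z: np.ndarray | float, t: float) -> np.ndarray | float:
    """Proximal operator of t*||.||_1: sign(z) * max(|z| - t, 0)."""
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def group_shrink(v: np.ndarray, t: float) -> np.ndarray:
    """Proximal operator of t*||.||_2: scale v by max(0, 1 - t/||v||)."""
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    v = np.asarray(v, dtype=float)
    norm = float(np.linalg.norm(v))
    if norm <= t:
        return np.zeros_like(v)
    return v * (1.0 - t / norm)


def _penalty_value(
    coeffs: np.ndarray, spec: PenaltySpec, lam1: float, lam2: float
) -> float:
    pen = 0.0
    if lam1 > 0:
        pen += lam1 * float(np.abs(coeffs).sum())
    if lam2 > 0 and spec.partition is not None:
        pen += lam2 * float(
            sum(np.linalg.norm(coeffs[g]) for g in spec.partition)
        )
    return pen


def objective_value(
    problem: RegressionProblem,
    coeffs: np.ndarray | CoefficientVector,
    spec: PenaltySpec,
    absolute_lambdas: tuple[float, float],
) -> float:
    """(1/2)||x - A alpha||^2 + lam1*||alpha||_1 + lam2*sum_g ||alpha_g||_2.

    ``absolute_lambdas`` are the absolute (lam1, lam2) values; whichever term
    the penalty kind lacks should be passed as 0.
    """
    a = coeffs.values if isinstance(coeffs, CoefficientVector) else np.asarray(coeffs, float)
    if a.shape[0] != problem.n_rois:
        raise ValueError("coefficient length must match design columns")
    resid = problem.response - problem.design @ a
    lam1, lam2 = absolute_lambdas
    return 0.5 * float(resid @ resid) + _penalty_value(a, spec, lam1, lam2)


def compute_lambda_max(
    problem: RegressionProblem, spec: PenaltySpec
) -> float | tuple[float, float]:
    """Smallest penalty level at which the all-zero solution is optimal.

    With loss (1/2)||x - A a||^2 the gradient at zero is -A^T x, so
    lambda_max is ``max_j |A_j^T x|`` for the l1 penalty and
    ``max_g ||A_g^T x||_2`` for the unweighted group penalty.  For sglasso the
    pair (l1 lambda_max, group lambda_max) is returned; each user ratio scales
    its own term, and either ratio at 1.0 suffices for the zero solution.
    """
    if float(np.var(problem.response)) == 0.0:
        raise ValueError("response has zero variance")
    grad0 = problem.design.T @ problem.response
    lam1_max = float(np.max(np.abs(grad0)))
    if spec.kind == "lasso":
        return lam1_max
    if spec.partition is None:
        raise ValueError("group penalties need a partition")
    lam2_max = float(max(np.linalg.norm(grad0[g]) for g in spec.partition))
    if spec.kind == "glasso":
        return lam2_max
    return lam1_max, lam2_max


def absolute_lambdas(
    problem: RegressionProblem, spec: PenaltySpec
) -> tuple[float, float]:
    """Resolve the penalty's ratios into absolute (lam1, lam2) values."""
    if spec.kind == "lasso":
        return spec.ratio_l1 * compute_lambda_max(problem, spec), 0.0
    if spec.kind == "glasso":
        return 0.0, spec.ratio_group * compute_lambda_max(problem, spec)
    lam1_max, lam2_max = compute_lambda_max(problem, spec)
    return spec.ratio_l1 * lam1_max, spec.ratio_group * lam2_max


def _prox(v: np.ndarray, spec: PenaltySpec, t1: float, t2: float) -> np.ndarray:
    """Prox of t1*||.||_1 + t2*sum_g||.||_2 (non-overlapping groups): soft
    threshold, then shrink each group."""
    out = soft_threshold(v, t1) if t1 > 0 else v.copy()
    if t2 > 0 and spec.partition is not None:
        for g in spec.partition:
            out[g] = group_shrink(out[g], t2)
    return out


def solve_sparse_regression(
    problem: RegressionProblem,
    spec: PenaltySpec,
    config: SolverConfig | None = None,
) -> CoefficientVector:
    """FISTA minimizer of the penalized least-squares objective.

    Uses the Gram formulation (gradient G a - b with G = A^T A, b = A^T x),
    a Lipschitz step 1/L with L the largest eigenvalue of G, and adaptive
    restart whenever the objective increases.  Coefficients with magnitude
    below ``zero_threshold`` are truncated to exact zeros and the centroid
    coefficient is forced to zero.
    """
    config = config or SolverConfig()
    spec.validate_partition(problem.n_rois, problem.centroid_index)
    lam1, lam2 = absolute_lambdas(problem, spec)

    A, x = problem.design, problem.response
    G = A.T @ A
    b = A.T @ x
    L = float(np.linalg.eigvalsh(G)[-1])
    if L <= 0:  # all-zero design: penalty alone, solution is zero
        return CoefficientVector(
            np.zeros(problem.n_rois), problem.centroid_index, True, 0,
            objective_value(problem, np.zeros(problem.n_rois), spec, (lam1, lam2)),
        )
    step = 1.0 / L
    half_xx = 0.5 * float(x @ x)

    def obj(a: np.ndarray) -> float:
        return (
            half_xx - float(b @ a) + 0.5 * float(a @ (G @ a))
            + _penalty_value(a, spec, lam1, lam2)
        )

    alpha = np.zeros(problem.n_rois)
    z = alpha.copy()
    t = 1.0
    f_prev = obj(alpha)
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        grad = G @ z - b
        alpha_new = _prox(z - step * grad, spec, step * lam1, step * lam2)
        alpha_new[problem.centroid_index] = 0.0
        f_new = obj(alpha_new)
        if f_new > f_prev:  # adaptive restart: drop momentum
            z = alpha.copy()
            t = 1.0
            grad = G @ z - b
            alpha_new = _prox(z - step * grad, spec, step * lam1, step * lam2)
            alpha_new[problem.centroid_index] = 0.0
            f_new = obj(alpha_new)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = alpha_new + ((t - 1.0) / t_new) * (alpha_new - alpha)
        alpha, t = alpha_new, t_new
        denom = max(abs(f_prev), 1.0)
        if abs(f_prev - f_new) / denom < config.tolerance:
            f_prev = f_new
            converged = True
            break
        f_prev = f_new
    if not converged:
        warnings.warn(
            f"solver did not converge in {config.max_iterations} iterations "
            f"(centroid {problem.centroid_index})",
            ConvergenceWarning,
            stacklevel=2,
        )
    alpha[np.abs(alpha) < config.zero_threshold] = 0.0
    alpha[problem.centroid_index] = 0.0
    return CoefficientVector(
        values=alpha,
        centroid_index=problem.centroid_index,
        converged=converged,
        n_iterations=it,
        objective=obj(alpha),
    )
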