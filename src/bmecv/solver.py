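"""Bayesian/Maximum-Entropy reweighting solver.

Given prior weights ``w0``, calculated observables ``s_ji`` (frame j,
observable i), targets ``y_i`` with uncertainties ``sigma_i`` and a
confidence hyperparameter ``theta > 0``, the solver minimizes

    L(w) = (m/2) * chi2_red(w) - theta * S_rel(w)

over the probability simplex, where ``chi2_red`` is the reduced chi-square
of the weighted averages and ``S_rel = -sum_j w_j ln(w_j / w0_j)``.

The optimization is carried out in the dual: optimal weights have the
exponential form  w_j ∝ w0_j * exp(-sum_i lambda_i s_ji)  and the m dual
parameters ``lambda`` minimize the convex function

    Gamma(lambda) = ln Z(lambda) + sum_i lambda_i y_i
                    + (theta/2) * sum_i sigma_i^2 lambda_i^2

whose gradient is  y_i - <s_i>_w(lambda) + theta sigma_i^2 lambda_i.
At the optimum the stationarity relation

    <s_i>_w - y_i = theta * sigma_i^2 * lambda_i

holds, linking residuals and dual parameters.  The dual form is verified
against brute-force primal minimization in the test suite.

Minimization uses a damped Newton iteration with an Armijo backtracking
line search; the Hessian is the weighted observable covariance plus
``theta * diag(sigma^2)``, which is positive definite for ``theta > 0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import scipy.linalg

from .ensemble import (
    ObservableMatrix,
    TargetSet,
    WeightVector,
    uniform_weights,
    weighted_observable_means,
)
from .errors import NumericError, ValidationError

__all__ = [
    "SolverSettings",
    "ReweightSolution",
    "chi2_red",
    "relative_entropy",
    "effective_sample_size",
    "apply_lambdas",
    "dual_value_and_gradient",
    "solve_bme",
    "lambda_rms",
    "kish_sample_size",
]


@dataclass
class SolverSettings:
    """Convergence controls for the dual minimization.

    grad_tol is the sup-norm of the dual gradient at convergence.
    lambda_init may be "zeros" or an explicit vector (used for warm starts
    along a theta scan).
    """

    grad_tol: float = 1e-8
    max_iter: int = 500
    lambda_init: Union[str, np.ndarray] = "zeros"
    warm_start: bool = False

    def __post_init__(self) -> None:
        if not self.grad_tol > 0:
            raise ValidationError("grad_tol must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")


@dataclass
class ReweightSolution:
    """One converged (or flagged) reweighting fit."""

    theta: float
    lambdas: np.ndarray
    weights: WeightVector
    chi2_red: float
    s_rel: float
    n_eff: float
    converged: bool
    n_iter: int

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "lambdas": [float(x) for x in self.lambdas],
            "chi2_red": self.chi2_red,
            "s_rel": self.s_rel,
            "n_eff": self.n_eff,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _check_alignment(matrix: ObservableMatrix, targets: TargetSet) -> None:
    if matrix.tags != targets.tags:
        raise ValidationError(
            "matrix and target tags differ; call align_by_tags first"
        )


def chi2_red(matrix: ObservableMatrix, w: WeightVector, targets: TargetSet) -> float:
    """Reduced chi-square of the weighted averages against the targets."""
    _check_alignment(matrix, targets)
    if len(targets) == 0:
        raise ValidationError("need at least one observable")
    means = weighted_observable_means(matrix, w)
    resid = (means - targets.values) / targets.sigmas
    return float(np.mean(resid**2))


def relative_entropy(w: WeightVector, w0: WeightVector) -> float:
    """Negative Kullback-Leibler divergence of w from w0 (always <= 0)."""
    if len(w) != len(w0):
        raise ValidationError("weight vectors must have equal length")
    wi = w.weights
    w0i = w0.weights
    active = wi > 0
    if np.any(w0i[active] <= 0):
        raise ValidationError("w must vanish wherever the prior w0 vanishes")
    s = -float(np.sum(wi[active] * np.log(wi[active] / w0i[active])))
    # clamp float round-off; S_rel is mathematically nonpositive
    return min(s, 0.0)


def effective_sample_size(s_rel: float) -> float:
    """Entropy-based effective sample fraction exp(s_rel), in (0, 1]."""
    if s_rel > 0:
        raise ValidationError(f"s_rel must be <= 0, got {s_rel}")
    return float(np.exp(s_rel))


def kish_sample_size(w: WeightVector) -> float:
    """Kish effective sample fraction 1 / (N * sum w^2).

    Auxiliary diagnostic only; the primary statistic is the entropy-based
    ``effective_sample_size``.
    """
    n = len(w)
    return float(1.0 / (n * np.sum(w.weights**2)))


def apply_lambdas(
    matrix: ObservableMatrix, lambdas: np.ndarray, w0: WeightVector
) -> WeightVector:
    """Exponential-family reweighting w_j ∝ w0_j exp(-sum_i lambda_i s_ji)."""
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.shape != (matrix.n_observables,):
        raise ValidationError(
            f"lambda length {lambdas.shape} does not match {matrix.n_observables} observables"
        )
    if len(w0) != matrix.n_frames:
        raise ValidationError("prior weight length does not match frame count")
    with np.errstate(divide="ignore"):
        logw = np.log(w0.weights) - matrix.values @ lambdas
    logw -= logw.max()
    w = np.exp(logw)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise NumericError("reweighting produced a non-finite or zero partition sum")
    return WeightVector(w / total, description="apply_lambdas")


def dual_value_and_gradient(
    lambdas: np.ndarray,
    matrix: ObservableMatrix,
    targets: TargetSet,
    theta: float,
    w0: WeightVector,
) -> tuple[float, np.ndarray]:
    """Convex dual objective Gamma(lambda) and its analytic gradient."""
    if not theta > 0:
        raise ValidationError("theta must be > 0")
    _check_alignment(matrix, targets)
    lambdas = np.asarray(lambdas, dtype=float)
    with np.errstate(divide="ignore"):
        a = np.log(w0.weights) - matrix.values @ lambdas
    shift = a.max()
    ez = np.exp(a - shift)
    z = ez.sum()
    if not np.isfinite(z) or z <= 0:
        raise NumericError("non-finite partition function in dual evaluation")
    log_z = shift + np.log(z)
    w = ez / z
    means = w @ matrix.values
    sig2 = targets.sigmas**2
    value = float(log_z + lambdas @ targets.values + 0.5 * theta * np.sum(sig2 * lambdas**2))
    grad = targets.values - means + theta * sig2 * lambdas
    return value, grad


def _dual_hessian(
    lambdas: np.ndarray,
    matrix: ObservableMatrix,
    targets: TargetSet,
    theta: float,
    w0: WeightVector,
) -> np.ndarray:
    w = apply_lambdas(matrix, lambdas, w0).weights
    means = w @ matrix.values
    centered = matrix.values - means
    cov = centered.T @ (w[:, None] * centered)
    return cov + theta * np.diag(targets.sigmas**2)


def solve_bme(
    matrix: ObservableMatrix,
    targets: TargetSet,
    theta: float,
    w0: WeightVector | None = None,
    settings: SolverSettings | None = None,
) -> ReweightSolution:
    """Minimize the dual and return weights plus fit statistics.

    Non-convergence within ``settings.max_iter`` is reported via
    ``converged=False``, never raised.
    """
    if not theta > 0:
        raise ValidationError("theta must be > 0 (use a small theta instead of 0)")
    _check_alignment(matrix, targets)
    if matrix.n_frames < 2:
        raise ValidationError("need at least 2 frames to reweight")
    if w0 is None:
        w0 = uniform_weights(matrix.n_frames)
    if len(w0) != matrix.n_frames:
        raise ValidationError("prior weight length does not match frame count")
    settings = settings or SolverSettings()

    m = matrix.n_observables
    if isinstance(settings.lambda_init, str):
        if settings.lambda_init != "zeros":
            raise ValidationError("lambda_init must be 'zeros' or a vector")
        lam = np.zeros(m)
    else:
        lam = np.array(settings.lambda_init, dtype=float)
        if lam.shape != (m,):
            raise ValidationError("lambda_init has wrong length")

    value, grad = dual_value_and_gradient(lam, matrix, targets, theta, w0)
    converged = bool(np.max(np.abs(grad)) <= settings.grad_tol)
    n_iter = 0
    while not converged and n_iter < settings.max_iter:
        hess = _dual_hessian(lam, matrix, targets, theta, w0)
        try:
            step = scipy.linalg.solve(hess, -grad, assume_a="pos")
        except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
            ridge = 1e-10 * max(1.0, float(np.trace(hess)) / m)
            step = scipy.linalg.solve(hess + ridge * np.eye(m), -grad)
        # Armijo backtracking on the convex dual
        slope = float(grad @ step)
        if slope >= 0:  # numerical safeguard: fall back to steepest descent
            step = -grad
            slope = -float(grad @ grad)
        noise_floor = 1e-13 * max(1.0, abs(value))
        if -slope <= noise_floor:
            # predicted decrease is below float rounding: take the pure
            # Newton step if it reduces the gradient sup-norm, else stall
            cand = lam + step
            cand_value, cand_grad = dual_value_and_gradient(
                cand, matrix, targets, theta, w0
            )
            if np.max(np.abs(cand_grad)) < np.max(np.abs(grad)):
                lam, value, grad = cand, cand_value, cand_grad
                n_iter += 1
                converged = bool(np.max(np.abs(grad)) <= settings.grad_tol)
                continue
            break
        t = 1.0
        accepted = False
        for _ in range(60):
            cand = lam + t * step
            cand_value, cand_grad = dual_value_and_gradient(
                cand, matrix, targets, theta, w0
            )
            if cand_value <= value + 1e-4 * t * slope:
                accepted = True
                break
            t *= 0.5
        if not accepted and np.max(np.abs(cand_grad)) >= np.max(np.abs(grad)):
            break  # line search exhausted without progress
        lam, value, grad = cand, cand_value, cand_grad
        n_iter += 1
        converged = bool(np.max(np.abs(grad)) <= settings.grad_tol)

    w = apply_lambdas(matrix, lam, w0)
    s_rel = relative_entropy(w, w0)
    return ReweightSolution(
        theta=float(theta),
        lambdas=lam,
        weights=w,
        chi2_red=chi2_red(matrix, w, targets),
        s_rel=s_rel,
        n_eff=effective_sample_size(s_rel),
        converged=converged,
        n_iter=n_iter,
    )


def lambda_rms(lambdas: np.ndarray) -> float:
    """Root mean square of the dual parameters."""
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size < 1:
        raise ValidationError("need at least one lambda")
    return float(np.sqrt(np.mean(lambdas**2)))
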