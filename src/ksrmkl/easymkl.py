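"""EasyMKL: learn kernel-combination weights from one quadratic program.

EasyMKL (Aiolli & Donini) finds the nonnegative combination of base
kernels that maximizes the separation between the convex hulls of the
two classes.  Its key property is that the full max-min problem over
weights and class distributions collapses to a single convex quadratic
program on the *average* trace-normalized kernel K^A:

    minimize   (1 - lambda) * gamma' Y K^A Y gamma + lambda * ||gamma||^2
    over       gamma in Gamma,

where Y = diag(labels) and Gamma is the product of the two class
simplices (nonnegative entries, positive-class entries summing to 1,
negative-class entries summing to 1) — each class contributes a
probability distribution.  lambda in [0, 1] trades margin against
regularization: lambda = 0 is the pure convex-hull-distance problem,
lambda = 1 yields the uniform per-class distribution.

From the optimum gamma* each base kernel's weight is the quadratic form

    eta_r = gamma*' Y (K_r / tr K_r) Y gamma*,

which is nonnegative for PSD kernels, and the combined kernel is
K_eta = sum_r eta_r * (K_r / tr K_r).

The QP is solved with an accelerated projected-gradient method (FISTA)
using exact Euclidean projection onto each class simplex; the problem
is smooth and convex, so this converges geometrically at the fixed step
1/L with L the Lipschitz constant of the gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kernels import KernelMatrix, KernelSet

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 0.1


@dataclass
class GammaSolution:
    gamma: np.ndarray
    lambda_reg: float
    objective_value: float
    solver_info: dict


@dataclass
class MKLWeights:
    """Per-kernel weights in KernelSet order.

    ``eta`` is the raw quadratic-form weight; ``normalized_eta`` is the
    same vector scaled to unit sum (reported alongside, since either
    convention reproduces the same ranking after SVM training).
    """

    eta: np.ndarray
    normalized_eta: np.ndarray


@dataclass
class CombinedKernel:
    values: np.ndarray
    weights_used: MKLWeights


@dataclass
class EasyMKLResult:
    weights: MKLWeights
    combined: CombinedKernel
    gamma: GammaSolution


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of v onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    ind = np.arange(1, len(v) + 1)
    cond = u - css / ind > 0
    rho = ind[cond][-1]
    theta = css[cond][-1] / rho
    return np.maximum(v - theta, 0.0)


def _project_gamma(g: np.ndarray, pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    out = np.empty_like(g)
    out[pos] = _project_simplex(g[pos])
    out[neg] = _project_simplex(g[neg])
    return out


def solve_gamma(
    K_avg: KernelMatrix | np.ndarray,
    labels: np.ndarray,
    lambda_reg: float = DEFAULT_LAMBDA,
    tol: float = 1e-8,
    max_iter: int = 50000,
) -> GammaSolution:
    """Solve the EasyMKL quadratic program over the paired class simplices.

    Parameters
    ----------
    K_avg : the (PSD) average trace-normalized kernel.
    labels : vector in {+1, -1}; both classes must be present.
    lambda_reg : regularization lambda in [0, 1].
    tol : convergence tolerance on the projected-gradient step.
    """
    K = K_avg.values if isinstance(K_avg, KernelMatrix) else np.asarray(K_avg, float)
    y = np.asarray(labels, dtype=np.float64)
    if set(np.unique(y)) - {1.0, -1.0}:
        raise ValueError("labels must be in {+1, -1}")
    pos, neg = y == 1, y == -1
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    if not 0.0 <= lambda_reg <= 1.0:
        raise ValueError("lambda_reg must lie in [0, 1]")
    n = len(y)
    M = K * np.outer(y, y)  # Y K Y
    M = (M + M.T) / 2.0

    def objective(g: np.ndarray) -> float:
        return float((1 - lambda_reg) * g @ M @ g + lambda_reg * g @ g)

    def gradient(g: np.ndarray) -> np.ndarray:
        return 2.0 * ((1 - lambda_reg) * (M @ g) + lambda_reg * g)

    # Lipschitz constant of the gradient
    lam_max = float(np.linalg.eigvalsh(M)[-1]) if n > 1 else float(M[0, 0])
    L = max(2.0 * ((1 - lambda_reg) * max(lam_max, 0.0) + lambda_reg), 1e-12)

    # uniform per-class start (the exact optimum when lambda = 1)
    g = np.empty(n)
    g[pos] = 1.0 / pos.sum()
    g[neg] = 1.0 / neg.sum()

    x = g.copy()
    z = g.copy()
    t = 1.0
    status, iterations = "max_iter", max_iter
    for it in range(1, max_iter + 1):
        x_new = _project_gamma(z - gradient(z) / L, pos, neg)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = x_new + (t - 1.0) / t_new * (x_new - x)
        step = float(np.max(np.abs(x_new - x)))
        x, t = x_new, t_new
        if step < tol:
            status, iterations = "converged", it
            break

    # snap numerically-zero entries and restore exact per-class sums
    x[x < 1e-12] = 0.0
    x[pos] /= x[pos].sum()
    x[neg] /= x[neg].sum()
    return GammaSolution(
        gamma=x,
        lambda_reg=lambda_reg,
        objective_value=objective(x),
        solver_info={"iterations": iterations, "status": status},
    )


def kernel_weights(
    gamma_solution: GammaSolution | np.ndarray,
    kernel_set: KernelSet,
    labels: np.ndarray,
) -> MKLWeights:
    """Per-kernel weights eta_r = gamma' Y (K_r / tr K_r) Y gamma."""
    g = (
        gamma_solution.gamma
        if isinstance(gamma_solution, GammaSolution)
        else np.asarray(gamma_solution, float)
    )
    y = np.asarray(labels, dtype=np.float64)
    if len(g) != len(y) or kernel_set.n_samples != len(y):
        raise ValueError("gamma, labels and kernels have mismatched sizes")
    gy = g * y
    eta = np.array([float(gy @ k.values @ gy) for k in kernel_set.normalized])
    if eta.min() < -1e-9:
        raise ValueError(f"negative kernel weight {eta.min()} — kernel not PSD?")
    eta = np.clip(eta, 0.0, None)
    total = eta.sum()
    normalized = eta / total if total > 0 else np.zeros_like(eta)
    return MKLWeights(eta=eta, normalized_eta=normalized)


def combine_kernels(
    kernel_set: KernelSet,
    weights: MKLWeights | np.ndarray,
    use_normalized: bool = True,
) -> CombinedKernel:
    """Weighted sum of the (by default trace-normalized) base kernels."""
    eta = weights.eta if isinstance(weights, MKLWeights) else np.asarray(weights, float)
    if len(eta) != len(kernel_set):
        raise ValueError("weight vector length != number of kernels")
    if eta.min() < 0:
        raise ValueError("kernel weights must be nonnegative")
    if not eta.any():
        logger.warning("all kernel weights are zero; combined kernel is degenerate")
    base = kernel_set.normalized if use_normalized else kernel_set.kernels
    values = np.zeros((kernel_set.n_samples, kernel_set.n_samples))
    for w, k in zip(eta, base):
        if w > 0:
            values += w * k.values
    if not isinstance(weights, MKLWeights):
        total = eta.sum()
        weights = MKLWeights(
            eta=eta, normalized_eta=eta / total if total > 0 else np.zeros_like(eta)
        )
    return CombinedKernel(values=values, weights_used=weights)


def combine_cross_kernels(
    kernel_set: KernelSet,
    weights: MKLWeights,
    test_view_matrices: dict[str, np.ndarray],
) -> np.ndarray:
    """n_test x n_train combined kernel for new samples.

    Each raw cross-kernel is divided by the *training* kernel's trace so
    that test rows live in the same combined space the SVM was trained in.
    """
    crosses = kernel_set.cross_kernels(test_view_matrices)
    traces = kernel_set.traces
    out = np.zeros_like(crosses[0])
    for w, C, tr in zip(weights.eta, crosses, traces):
        if w > 0:
            out += w * C / tr
    return out


def fit_easymkl(
    kernel_set: KernelSet,
    labels: np.ndarray,
    lambda_reg: float = DEFAULT_LAMBDA,
) -> EasyMKLResult:
    """Full EasyMKL pass: solve for gamma on K^A, read off the weights,
    and build the combined kernel."""
    gamma = solve_gamma(kernel_set.average, labels, lambda_reg)
    weights = kernel_weights(gamma, kernel_set, labels)
    combined = combine_kernels(kernel_set, weights)
    return EasyMKLResult(weights=weights, combined=combined, gamma=gamma)
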