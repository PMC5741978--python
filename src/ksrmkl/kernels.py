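"""RBF base-kernel construction, trace normalization and the average kernel.

Each feature view X (n x |F_n|) yields one RBF kernel per bandwidth
parameter beta:

    K(x_i, x_j) = exp(-beta / |F_n| * ||x_i - x_j||^2)

where |F_n| is the number of features of the view, so that the exponent
is on a comparable scale across views of very different dimensionality.
With the default beta grid {1,...,5} and two views the base-kernel set
holds 10 kernels, ordered view-major / beta-minor; this ordering is
frozen so learned weight vectors are reproducible.  Trace normalization
(K / tr K) puts heterogeneous kernels on a common scale; the average of
the trace-normalized kernels, K^A, drives the kernel-weight optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances

DEFAULT_BETAS = (1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass
class KernelMatrix:
    values: np.ndarray
    provenance: tuple[str, float] | str  # (view, beta) or "average"/"combined"


@dataclass
class KernelSet:
    """Ordered base kernels plus trace-normalized forms and the average K^A.

    ``view_matrices`` keeps the training feature matrices so that
    cross-kernels for new samples can be rebuilt with the training
    feature counts.
    """

    kernels: list[KernelMatrix]
    normalized: list[KernelMatrix]
    average: KernelMatrix
    betas: tuple[float, ...]
    views: tuple[str, ...]
    view_matrices: dict[str, np.ndarray]

    def __len__(self) -> int:
        return len(self.kernels)

    @property
    def n_samples(self) -> int:
        return self.kernels[0].values.shape[0]

    @property
    def traces(self) -> np.ndarray:
        return np.array([np.trace(k.values) for k in self.kernels])

    def cross_kernels(self, test_view_matrices: dict[str, np.ndarray]) -> list[np.ndarray]:
        """Raw n_test x n_train kernels aligned with the base-kernel
        order, using each view's training feature count."""
        out = []
        for view in self.views:
            X_train = self.view_matrices[view]
            X_test = test_view_matrices[view]
            if X_test.shape[1] != X_train.shape[1]:
                raise ValueError(
                    f"view {view!r}: test feature count {X_test.shape[1]} "
                    f"!= training {X_train.shape[1]}"
                )
            d2 = euclidean_distances(X_test, X_train, squared=True)
            np.clip(d2, 0.0, None, out=d2)
            for beta in self.betas:
                out.append(np.exp(-beta / X_train.shape[1] * d2))
        return out


def rbf_kernel(X: np.ndarray, beta: float, provenance: str = "view") -> KernelMatrix:
    """RBF kernel with the exponent scaled by the feature count |F_n|."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be n x |F_n| with |F_n| >= 1")
    if beta <= 0:
        raise ValueError("beta must be positive")
    d2 = euclidean_distances(X, squared=True)
    np.clip(d2, 0.0, None, out=d2)  # guard tiny negatives from the Gram expansion
    np.fill_diagonal(d2, 0.0)
    K = np.exp(-beta / X.shape[1] * d2)
    K = (K + K.T) / 2.0
    return KernelMatrix(values=K, provenance=(provenance, float(beta)))


def rbf_cross_kernel(
    X_test: np.ndarray, X_train: np.ndarray, beta: float
) -> np.ndarray:
    """n_test x n_train RBF kernel using the training feature count."""
    if X_test.shape[1] != X_train.shape[1]:
        raise ValueError("feature-count mismatch between test and train")
    d2 = euclidean_distances(X_test, X_train, squared=True)
    np.clip(d2, 0.0, None, out=d2)
    return np.exp(-beta / X_train.shape[1] * d2)


def trace_normalize(K: KernelMatrix | np.ndarray) -> KernelMatrix:
    """Divide a kernel by its trace so that tr(K) = 1."""
    values = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    provenance = K.provenance if isinstance(K, KernelMatrix) else "matrix"
    tr = float(np.trace(values))
    if tr <= 0:
        raise ValueError(f"non-positive trace {tr}: not a valid kernel")
    return KernelMatrix(values=values / tr, provenance=provenance)


def kernel_set_from_kernels(
    kernels: list[KernelMatrix],
    views: tuple[str, ...] = (),
    betas: tuple[float, ...] = (),
    view_matrices: dict[str, np.ndarray] | None = None,
) -> KernelSet:
    """Assemble a :class:`KernelSet` from explicit kernel matrices,
    computing the trace-normalized copies and the average kernel."""
    if not kernels:
        raise ValueError("at least one kernel is required")
    normalized = [trace_normalize(k) for k in kernels]
    avg = np.mean([k.values for k in normalized], axis=0)
    return KernelSet(
        kernels=kernels,
        normalized=normalized,
        average=KernelMatrix(values=avg, provenance="average"),
        betas=betas,
        views=views,
        view_matrices=view_matrices or {},
    )


def build_kernel_set(
    view_matrices: dict[str, np.ndarray],
    betas: tuple[float, ...] = DEFAULT_BETAS,
) -> KernelSet:
    """Build the full base-kernel set for the given views.

    One kernel per (view, beta) pair, views in dict order (outer), betas
    in grid order (inner).  Trace-normalized copies and the average
    kernel K^A = (1/R) * sum_r K_r / tr(K_r) are computed eagerly.
    """
    if not view_matrices:
        raise ValueError("at least one view is required")
    if not betas:
        raise ValueError("beta grid must be non-empty")
    n_set = {m.shape[0] for m in view_matrices.values()}
    if len(n_set) != 1:
        raise ValueError(f"views have mismatched sample counts: {sorted(n_set)}")
    kernels: list[KernelMatrix] = []
    for view, X in view_matrices.items():
        d2 = euclidean_distances(X, squared=True)
        np.clip(d2, 0.0, None, out=d2)
        np.fill_diagonal(d2, 0.0)
        for beta in betas:
            K = np.exp(-beta / X.shape[1] * d2)
            K = (K + K.T) / 2.0
            kernels.append(KernelMatrix(values=K, provenance=(view, float(beta))))
    normalized = [trace_normalize(k) for k in kernels]
    avg = np.mean([k.values for k in normalized], axis=0)
    return KernelSet(
        kernels=kernels,
        normalized=normalized,
        average=KernelMatrix(values=avg, provenance="average"),
        betas=tuple(float(b) for b in betas),
        views=tuple(view_matrices),
        view_matrices={v: np.asarray(m, dtype=np.float64) for v, m in view_matrices.items()},
    )
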