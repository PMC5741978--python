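"""Soft-margin SVM on the precomputed combined kernel.

The classifier solves the usual soft-margin problem

    min_{f,b,xi}  1/2 ||f||_H^2 + C sum_i xi_i
    s.t.          y_i (f(x_i) + b) >= 1 - xi_i,  xi_i >= 0

in the RKHS of the combined kernel K_eta, and scores a sample x with

    f(x) = sum_i alpha_i* k_eta(x, x_i) + b*

where alpha_i* are the signed dual coefficients (zero off the support
vectors).  The dual is solved with scikit-learn's precomputed-kernel
SVC; the box constraint 0 <= |alpha_i| <= C and the dual equality
constraint are checked after every fit.

``predict_sites`` carries a full kernel recipe (training feature
matrices, beta grid, MKL weights, flank, partner universe) so that new
phosphosites can be encoded and scored against a trained model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import easymkl, kernels
from .data_io import PPINetwork, ProteinSequenceSet, SiteRecord
from .easymkl import EasyMKLResult, MKLWeights
from .features import ALPHABET, encode_function, encode_window, extract_window
from .kernels import KernelSet

DEFAULT_C = 1.0


@dataclass
class KernelRecipe:
    """Everything needed to rebuild cross-kernels for new samples."""

    views: tuple[str, ...]
    betas: tuple[float, ...]
    eta: np.ndarray
    train_view_matrices: dict[str, np.ndarray]
    flank: int
    ppi_mode: str
    partner_universe: list[str]
    alphabet: str = ALPHABET


@dataclass
class SVMModel:
    alphas: np.ndarray  # signed dual coefficients alpha_i* (zero off support)
    bias: float
    C: float
    support_indices: np.ndarray
    training_labels: np.ndarray
    kernel_recipe: KernelRecipe | None = field(default=None, repr=False)


def train_svm(
    combined_kernel: np.ndarray | easymkl.CombinedKernel,
    labels: np.ndarray,
    C: float = DEFAULT_C,
    tol: float = 1e-7,
) -> SVMModel:
    """Fit the dual soft-margin SVM on a precomputed kernel.

    Returns the full-length signed dual-coefficient vector, the bias,
    and the support indices; KKT box/equality conditions are asserted.
    """
    K = (
        combined_kernel.values
        if isinstance(combined_kernel, easymkl.CombinedKernel)
        else np.asarray(combined_kernel, dtype=np.float64)
    )
    y = np.asarray(labels, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train an SVM")
    if C <= 0:
        raise ValueError("C must be positive")
    svc = SVC(kernel="precomputed", C=C, tol=tol)
    svc.fit(K, y)
    alphas = np.zeros(len(y))
    alphas[svc.support_] = svc.dual_coef_[0]
    bias = float(svc.intercept_[0])
    # dual feasibility: |alpha_i| <= C, signs match labels, equality constraint
    if np.max(np.abs(alphas)) > C * (1 + 1e-8):
        raise RuntimeError("dual solution violates the box constraint")
    if abs(alphas.sum()) > 1e-6 * max(1.0, C):
        raise RuntimeError("dual equality constraint violated")
    return SVMModel(
        alphas=alphas,
        bias=bias,
        C=C,
        support_indices=svc.support_.copy(),
        training_labels=y.copy(),
    )


def decision_scores(model: SVMModel, cross_kernel: np.ndarray) -> np.ndarray:
    """Continuous decision values f(x) = sum_i alpha_i* k(x, x_i) + b*."""
    cross_kernel = np.asarray(cross_kernel, dtype=np.float64)
    if cross_kernel.ndim != 2 or cross_kernel.shape[1] != len(model.alphas):
        raise ValueError(
            f"cross kernel must be n_test x {len(model.alphas)}, "
            f"got {cross_kernel.shape}"
        )
    return cross_kernel @ model.alphas + model.bias


def fit_pipeline(
    view_matrices: dict[str, np.ndarray],
    labels: np.ndarray,
    betas: tuple[float, ...] = kernels.DEFAULT_BETAS,
    lambda_reg: float = easymkl.DEFAULT_LAMBDA,
    C: float = DEFAULT_C,
) -> tuple[SVMModel, KernelSet, EasyMKLResult]:
    """Base kernels -> EasyMKL weights -> combined kernel -> SVM."""
    kernel_set = kernels.build_kernel_set(view_matrices, betas)
    mkl = easymkl.fit_easymkl(kernel_set, labels, lambda_reg)
    model = train_svm(mkl.combined, labels, C)
    return model, kernel_set, mkl


def score_new_samples(
    model: SVMModel,
    kernel_set: KernelSet,
    weights: MKLWeights,
    test_view_matrices: dict[str, np.ndarray],
) -> np.ndarray:
    cross = easymkl.combine_cross_kernels(kernel_set, weights, test_view_matrices)
    return decision_scores(model, cross)


def _encode_new_sites(
    sites: list[SiteRecord],
    sequences: ProteinSequenceSet,
    ppi: PPINetwork | None,
    recipe: KernelRecipe,
) -> tuple[dict[str, np.ndarray], list[int], list[tuple[SiteRecord, str]]]:
    """Encode predictable sites with the training recipe.

    Unseen PPI partners are ignored by projecting onto the training
    partner universe; substrates missing a sequence yield per-site
    errors instead of aborting the run.
    """
    universe = recipe.partner_universe
    index = {p: i for i, p in enumerate(universe)}
    seq_rows, func_rows, kept, failed = [], [], [], []
    for i, site in enumerate(sites):
        if site.substrate_id not in sequences:
            failed.append((site, "missing substrate sequence"))
            continue
        seq = sequences[site.substrate_id]
        if not 1 <= site.position <= len(seq):
            failed.append((site, f"position {site.position} outside sequence"))
            continue
        seq_rows.append(encode_window(extract_window(seq, site.position, recipe.flank)))
        if "func" in recipe.views:
            vec = np.zeros(len(universe))
            neighbors = ppi.neighbors(site.substrate_id) if ppi is not None else {}
            for partner, score in neighbors.items():
                j = index.get(partner)
                if j is not None:
                    vec[j] = 1.0 if recipe.ppi_mode == "binary" else score / 1000.0
            func_rows.append(vec)
        kept.append(i)
    matrices: dict[str, np.ndarray] = {}
    if kept:
        if "seq" in recipe.views:
            matrices["seq"] = np.vstack(seq_rows)
        if "func" in recipe.views:
            matrices["func"] = np.vstack(func_rows)
    return matrices, kept, failed


def predict_sites(
    model: SVMModel,
    new_sites: list[SiteRecord],
    sequences: ProteinSequenceSet,
    ppi: PPINetwork | None = None,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Score new phosphosites with a trained model.

    Returns a table (substrate_id, position, residue, score, call,
    error) sorted by descending score, ties broken by input order.
    Sites that cannot be encoded get an error entry with NaN score.
    """
    recipe = model.kernel_recipe
    if recipe is None:
        raise ValueError("model carries no kernel recipe; cannot encode new sites")
    kernel_set = kernels.build_kernel_set(
        {v: recipe.train_view_matrices[v] for v in recipe.views}, recipe.betas
    )
    weights_sum = recipe.eta.sum()
    weights = MKLWeights(
        eta=recipe.eta,
        normalized_eta=recipe.eta / weights_sum if weights_sum > 0 else recipe.eta,
    )
    matrices, kept, failed = _encode_new_sites(new_sites, sequences, ppi, recipe)
    rows = []
    if kept:
        scores = score_new_samples(model, kernel_set, weights, matrices)
        for idx, score in zip(kept, scores):
            site = new_sites[idx]
            rows.append(
                {
                    "substrate_id": site.substrate_id,
                    "position": site.position,
                    "residue": site.residue,
                    "score": float(score),
                    "call": bool(score >= threshold),
                    "error": "",
                }
            )
    for site, msg in failed:
        rows.append(
            {
                "substrate_id": site.substrate_id,
                "position": site.position,
                "residue": site.residue,
                "score": float("nan"),
                "call": False,
                "error": msg,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["substrate_id", "position", "residue", "score", "call", "error"]
    )
    if len(frame):
        frame = frame.sort_values(
            "score", ascending=False, kind="stable", na_position="last"
        ).reset_index(drop=True)
    return frame


def save_model(model: SVMModel, path: str | Path, extra: dict | None = None) -> Path:
    """Serialize a model (with its kernel recipe) to a JSON archive."""
    recipe = model.kernel_recipe
    if recipe is None:
        raise ValueError("only models with a kernel recipe can be archived")
    payload = {
        "alphas": model.alphas.tolist(),
        "bias": model.bias,
        "C": model.C,
        "support_indices": model.support_indices.tolist(),
        "training_labels": model.training_labels.tolist(),
        "recipe": {
            "views": list(recipe.views),
            "betas": list(recipe.betas),
            "eta": recipe.eta.tolist(),
            "train_view_matrices": {
                v: m.tolist() for v, m in recipe.train_view_matrices.items()
            },
            "flank": recipe.flank,
            "ppi_mode": recipe.ppi_mode,
            "partner_universe": recipe.partner_universe,
            "alphabet": recipe.alphabet,
        },
        "extra": extra or {},
    }
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def load_model(path: str | Path) -> tuple[SVMModel, dict]:
    payload = json.loads(Path(path).read_text())
    r = payload["recipe"]
    recipe = KernelRecipe(
        views=tuple(r["views"]),
        betas=tuple(r["betas"]),
        eta=np.array(r["eta"], dtype=float),
        train_view_matrices={
            v: np.array(m, dtype=float) for v, m in r["train_view_matrices"].items()
        },
        flank=int(r["flank"]),
        ppi_mode=r["ppi_mode"],
        partner_universe=list(r["partner_universe"]),
        alphabet=r["alphabet"],
    )
    model = SVMModel(
        alphas=np.array(payload["alphas"], dtype=float),
        bias=float(payload["bias"]),
        C=float(payload["C"]),
        support_indices=np.array(payload["support_indices"], dtype=int),
        training_labels=np.array(payload["training_labels"], dtype=float),
        kernel_recipe=recipe,
    )
    return model, payload.get("extra", {})
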