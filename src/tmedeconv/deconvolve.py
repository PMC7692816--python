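"""Constrained non-negative matrix factorization for cell-type deconvolution.

The bulk expression matrix X (genes x samples) is modelled as the product
of a non-negative signature matrix S (genes x types) and a non-negative
relative-proportion matrix P (types x samples).  Prior marker knowledge
enters through a labeling matrix C with entries in [0, 1]: the objective

    || X - S P ||_F^2  +  lambda * sum_{g,k} S[g,k] * (1 - C[g,k])

penalizes signature mass on genes that are not labeled markers of the
type, i.e. an L1 penalty on off-marker signature entries.  As lambda grows
the signatures concentrate on the labeled markers; at lambda = 0 the
problem is plain NMF.

Optimization uses multiplicative updates (the Frobenius-loss scheme with
the linear penalty absorbed into the S update), which keep both factors
non-negative and never increase the objective.  Scale ambiguity is
resolved by convention: after fitting, each column of S is L1-normalized
and P is rescaled compensatingly, leaving the product unchanged.

Relative proportions, not absolute fractions, are what the model
identifies; an optional per-sample sum-to-one renormalization is provided
for plotting-style output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

from .containers import ExpressionMatrix, MarkerSet, ValidationError
from .markers import LabelingMatrix

__all__ = [
    "DeconvolutionResult",
    "FunctionActivity",
    "constrained_nmf",
    "proportions_from_markers",
    "estimate_functions",
    "lambda_sensitivity",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class DeconvolutionResult:
    """Fitted factors and diagnostics of one constrained-NMF run."""

    S: np.ndarray  # genes x types, columns L1-normalized
    P: np.ndarray  # types x samples
    gene_ids: list[str]
    type_names: list[str]
    sample_ids: list[str]
    lambda_: float
    objective_trace: np.ndarray
    converged: bool
    n_iter: int

    def proportions_sum_to_one(self) -> np.ndarray:
        """P with each sample column renormalized to sum to one."""
        col = self.P.sum(axis=0, keepdims=True)
        col[col == 0] = 1.0
        return self.P / col


@dataclass
class FunctionActivity:
    """Per-sample activity of one cell-type-specific function."""

    type_name: str
    function_name: str
    sample_ids: list[str]
    activity: np.ndarray


def _objective(X, S, P, lambda_, penalty_mask) -> float:
    resid = X - S @ P
    return float(np.sum(resid * resid) + lambda_ * np.sum(S * penalty_mask))


def _nnls_columns(S: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Solve min ||X - S P|| for P >= 0, one sample column at a time."""
    P = np.empty((S.shape[1], X.shape[1]))
    for j in range(X.shape[1]):
        P[:, j], _ = nnls(S, X[:, j])
    return P


def constrained_nmf(
    X: ExpressionMatrix,
    C: LabelingMatrix,
    lambda_: float | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
    init: str = "marker_mean",
    seed: int = 0,
) -> DeconvolutionResult:
    """Fit marker-constrained NMF on the genes shared by ``X`` and ``C``.

    Parameters
    ----------
    X
        Linear-scale expression (genes x samples).
    C
        Labeling matrix; the factorization rank is its number of types.
    lambda_
        Off-marker penalty weight; default ``mean(X)``, which puts the
        penalty on the scale of a typical expression value.
    init
        ``marker_mean`` (default) initializes each signature column from
        the mean expression of that type's labeled genes (with a small
        floor) and P by non-negative least squares; ``random`` draws both
        factors from a seeded uniform distribution.
    """
    shared = [g for g in C.gene_ids if X.has_gene(g)]
    if not shared:
        raise ValidationError("no genes shared between X and the labeling matrix")
    Xs = X.subset_genes(shared)
    keep = [C.gene_ids.index(g) for g in shared]
    Cv = C.values[keep, :]
    A = Xs.values
    nonzero_rows = A.sum(axis=1) > 0
    if not np.all(nonzero_rows):
        dropped = [g for g, ok in zip(Xs.gene_ids, nonzero_rows) if not ok]
        logger.warning("dropping %d all-zero gene rows: %s", len(dropped), dropped[:5])
        A = A[nonzero_rows]
        Cv = Cv[nonzero_rows]
        shared = [g for g, ok in zip(Xs.gene_ids, nonzero_rows) if ok]
    n_genes, n_samples = A.shape
    n_types = Cv.shape[1]
    if lambda_ is None:
        lambda_ = float(A.mean())
    if lambda_ < 0:
        raise ValidationError("lambda_ must be non-negative")

    rng = np.random.default_rng(seed)
    if init == "marker_mean":
        S = np.empty((n_genes, n_types))
        for k in range(n_types):
            mask = Cv[:, k] > 0
            if not np.any(mask):
                raise ValidationError(
                    f"type {C.type_names[k]!r} has no labeled genes in X"
                )
            S[:, k] = A.mean(axis=1) * (Cv[:, k] > 0)
        S += 1e-6
        P = _nnls_columns(S, A) + 1e-9
    elif init == "random":
        scale = np.sqrt(A.mean() / n_types)
        S = rng.uniform(0.1, 1.0, size=(n_genes, n_types)) * scale
        P = rng.uniform(0.1, 1.0, size=(n_types, n_samples)) * scale
    else:
        raise ValueError(f"unknown init {init!r}")

    penalty_mask = 1.0 - Cv
    trace = [_objective(A, S, P, lambda_, penalty_mask)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # multiplicative update for S with the linear penalty in the denominator
        numer = A @ P.T
        denom = S @ (P @ P.T) + 0.5 * lambda_ * penalty_mask + _EPS
        S = S * (numer / denom)
        # multiplicative update for P
        numer = S.T @ A
        denom = (S.T @ S) @ P + _EPS
        P = P * (numer / denom)
        obj = _objective(A, S, P, lambda_, penalty_mask)
        prev = trace[-1]
        trace.append(obj)
        if obj > prev * (1 + 1e-9) + 1e-9:
            raise ArithmeticError(
                f"objective increased at iteration {it}: {prev} -> {obj}; "
                f"trace={trace[-5:]}"
            )
        if prev > 0 and (prev - obj) / prev < tol:
            converged = True
            break

    # resolve scale ambiguity: L1-normalize signature columns
    norms = S.sum(axis=0)
    norms[norms == 0] = 1.0
    S = S / norms
    P = P * norms[:, None]

    return DeconvolutionResult(
        S=S,
        P=P,
        gene_ids=list(shared),
        type_names=list(C.type_names),
        sample_ids=list(Xs.sample_ids),
        lambda_=float(lambda_),
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
    )


def proportions_from_markers(
    X: ExpressionMatrix, marker_sets: Sequence[MarkerSet]
) -> tuple[np.ndarray, list[str]]:
    """Fast marker-average activity: the degenerate fixed-signature case.

    Row k is the arithmetic mean of ``log2(x + 1)``-transformed expression
    of set k's genes in each sample.  Returns ``(types x samples, names)``.
    """
    L = X.log2_values()
    rows = []
    for ms in marker_sets:
        idx = X.gene_indices(ms.genes)
        if not idx:
            raise ValidationError(f"no genes of set {ms.name!r} present in X")
        rows.append(L[idx, :].mean(axis=0))
    return np.vstack(rows), [ms.name for ms in marker_sets]


def estimate_functions(
    X: ExpressionMatrix,
    result: DeconvolutionResult,
    function_markers: Mapping[tuple[str, str], Sequence[str]],
    rank1_iters: int = 200,
) -> list[FunctionActivity]:
    """Second-round NMF for cell-type-specific functional activities.

    Each ``(type, function)`` marker set is assumed to contain genes whose
    expression is specific to the type (the screening that selects
    function markers enforces this), so their bulk expression tracks
    ``proportion(type) * intensity(function)``.  A rank-1 NMF of the
    function genes' expression yields a per-sample loading; dividing by
    the type's estimated proportion reports the intensity per unit of
    cell type, on the same relative scale as P.  Explicit residualization
    against the other cell types' proportions is deliberately not
    performed: proportion rows are compositional (they share a large
    common component), so an unpenalized non-negative regression absorbs
    much of the target signal and the clipped residual loses it.
    """
    out: list[FunctionActivity] = []
    type_row = {t: i for i, t in enumerate(result.type_names)}
    for (type_name, function_name), genes in function_markers.items():
        if type_name not in type_row:
            raise ValidationError(f"type {type_name!r} not present in result")
        idx = X.gene_indices(genes)
        if not idx:
            logger.warning(
                "no genes found for function %r of type %r; skipped",
                function_name,
                type_name,
            )
            continue
        resid = X.values[idx, :]
        k = type_row[type_name]
        # rank-1 NMF by alternating non-negative least squares
        u = np.clip(resid.mean(axis=1), _EPS, None)
        v = np.zeros(resid.shape[1])
        for _ in range(rank1_iters):
            v_new = np.clip(u @ resid / (u @ u + _EPS), 0.0, None)
            u_new = np.clip(resid @ v_new / (v_new @ v_new + _EPS), 0.0, None)
            if np.allclose(u_new, u) and np.allclose(v_new, v):
                u, v = u_new, v_new
                break
            u, v = u_new, v_new
        # scale so the gene loading sums to one, matching P's convention
        s = u.sum()
        if s > 0:
            v = v * s
        p_k = result.P[k, :]
        activity = v / (p_k + _EPS)
        out.append(
            FunctionActivity(
                type_name=type_name,
                function_name=function_name,
                sample_ids=list(result.sample_ids),
                activity=activity,
            )
        )
    return out


def lambda_sensitivity(
    X: ExpressionMatrix,
    C: LabelingMatrix,
    lambdas: Sequence[float],
    **kwargs,
) -> list[DeconvolutionResult]:
    """Refit across a penalty sweep; a documented sensitivity utility."""
    return [constrained_nmf(X, C, lambda_=lam, **kwargs) for lam in lambdas]
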