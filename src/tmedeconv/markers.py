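"""Marker-guided discovery of detectable cell components in a dataset.

Three steps precede deconvolution:

1. A *labeling matrix* stores prior marker evidence: entry (gene, type) is
   positive when the gene is a known marker of the type, and higher values
   mean stronger prior evidence of elevated expression in that type.
2. The number of cell components actually detectable in the dataset is
   estimated by bi-cross-validation (BCV): rows and columns are split into
   blocks, and the held-out block is predicted from the three training
   blocks through a rank-r truncated factorization (the Owen-Perry
   scheme).  The selected rank minimizes mean held-out squared error.
3. Dataset-specific marker modules are refined by nonparametric hub/module
   detection: within each type's prior marker list, the hub is the gene
   with the largest summed Spearman correlation to the others, and the
   module keeps genes sufficiently correlated with the hub.  Types whose
   surviving module is too small are reported undetectable in the dataset.

Refinement only filters the prior list — it never invents new markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .containers import (
    ExpressionMatrix,
    MarkerSet,
    ValidationError,
    normalize_gene_id,
)

__all__ = [
    "LabelingMatrix",
    "MarkerModule",
    "build_labeling_matrix",
    "estimate_rank_bcv",
    "detect_marker_modules",
]

logger = logging.getLogger(__name__)


@dataclass
class LabelingMatrix:
    """Prior marker evidence: genes x types, values in [0, 1]."""

    gene_ids: list[str]
    type_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.type_names)):
            raise ValidationError("labeling matrix shape mismatch")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValidationError("labeling values must lie in [0, 1]")
        empty = [
            t
            for j, t in enumerate(self.type_names)
            if not np.any(self.values[:, j] > 0)
        ]
        if empty:
            raise ValidationError(
                f"types with no positive labeling entries: {empty}"
            )

    def restrict_types(self, keep: Sequence[str]) -> "LabelingMatrix":
        idx = [self.type_names.index(t) for t in keep]
        return LabelingMatrix(
            list(self.gene_ids), list(keep), self.values[:, idx].copy()
        )


@dataclass
class MarkerModule:
    """A refined, dataset-specific co-expression module for one type."""

    type_name: str
    hub_gene: str
    member_genes: list[str]
    mean_internal_correlation: float

    def __post_init__(self) -> None:
        if self.hub_gene not in self.member_genes:
            raise ValidationError("hub gene must be a module member")


def build_labeling_matrix(
    marker_sets: Sequence[MarkerSet],
    gene_universe: Sequence[str],
    prior_weight: float = 1.0,
) -> LabelingMatrix:
    """Spread prior marker sets over a gene universe.

    Entry (g, k) equals ``prior_weight`` when gene g belongs to the k-th
    marker set and 0 otherwise.  Marker genes absent from the universe are
    dropped with a logged warning; a type losing all of its markers is an
    error.
    """
    if not 0 < prior_weight <= 1:
        raise ValidationError("prior_weight must lie in (0, 1]")
    if len(gene_universe) == 0:
        raise ValidationError("gene universe is empty")
    names = [ms.name for ms in marker_sets]
    if len(set(names)) != len(names):
        raise ValidationError("marker set names must be unique")
    uni_index = {normalize_gene_id(g): i for i, g in enumerate(gene_universe)}
    values = np.zeros((len(gene_universe), len(marker_sets)))
    for k, ms in enumerate(marker_sets):
        hit = 0
        for g in ms.genes:
            i = uni_index.get(normalize_gene_id(g))
            if i is None:
                logger.warning(
                    "marker %r of type %r absent from gene universe", g, ms.name
                )
                continue
            values[i, k] = prior_weight
            hit += 1
        if hit == 0:
            raise ValidationError(
                f"no markers of type {ms.name!r} present in the gene universe"
            )
    return LabelingMatrix(list(map(str, gene_universe)), names, values)


def estimate_rank_bcv(
    X: ExpressionMatrix | np.ndarray,
    max_rank: int,
    n_folds: int = 2,
    n_reps: int = 20,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Select a factorization rank by bi-cross-validation.

    For each repetition, rows and columns are randomly partitioned into
    ``n_folds`` folds.  Every (row-fold, column-fold) pair defines a
    held-out block X22; it is predicted from the three training blocks as
    ``X21 @ pinv_r(X11) @ X12`` where ``pinv_r`` is the pseudo-inverse of
    the rank-r truncated SVD of X11.  Errors are mean squared per held-out
    entry, averaged over blocks and repetitions.  The selected rank is the
    smallest rank whose error is within numerical tolerance of the
    minimum, so exact ties (noiseless data above its true rank) resolve to
    the true rank.

    Returns ``(selected_rank, per_rank_errors)`` with errors indexed by
    rank 1..max_rank.
    """
    A = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    n, m = A.shape
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    if max_rank < 1 or max_rank >= min(n, m) / 2:
        raise ValidationError(
            f"max_rank must satisfy 1 <= max_rank < min(n_genes, n_samples)/2 "
            f"= {min(n, m) / 2:g}"
        )
    rng = np.random.default_rng(seed)
    errors = np.zeros(max_rank)
    n_blocks = 0
    for _ in range(n_reps):
        for _attempt in range(10):
            row_fold = rng.permutation(np.arange(n) % n_folds)
            col_fold = rng.permutation(np.arange(m) % n_folds)
            ok = all(np.sum(row_fold == f) > max_rank for f in range(n_folds)) and all(
                np.sum(col_fold == f) > max_rank for f in range(n_folds)
            )
            if ok:
                break
        else:
            raise ValidationError(
                "could not build a non-degenerate BCV partition in 10 tries"
            )
        for fr in range(n_folds):
            for fc in range(n_folds):
                hold_r = row_fold == fr
                hold_c = col_fold == fc
                X11 = A[np.ix_(~hold_r, ~hold_c)]
                X12 = A[np.ix_(~hold_r, hold_c)]
                X21 = A[np.ix_(hold_r, ~hold_c)]
                X22 = A[np.ix_(hold_r, hold_c)]
                u, s, vt = np.linalg.svd(X11, full_matrices=False)
                for r in range(1, max_rank + 1):
                    rr = min(r, int(np.sum(s > 0)))
                    if rr == 0:
                        pred = np.zeros_like(X22)
                    else:
                        pinv = vt[:rr].T @ np.diag(1.0 / s[:rr]) @ u[:, :rr].T
                        pred = X21 @ pinv @ X12
                    errors[r - 1] += np.mean((X22 - pred) ** 2)
                n_blocks += 1
    errors /= n_blocks
    scale = np.mean(A**2)
    tol = 1e-10 * scale + (1e-6) * errors.min()
    selected = int(np.argmax(errors <= errors.min() + tol)) + 1
    return selected, errors


def detect_marker_modules(
    X: ExpressionMatrix,
    labeling: LabelingMatrix,
    corr_threshold: float = 0.5,
    min_module_size: int = 3,
) -> list[MarkerModule]:
    """Refine prior marker lists into dataset-specific co-expression modules.

    For each type, the Spearman co-expression matrix of its labeled genes
    (those present in ``X``) is computed; constant genes are excluded with
    a warning.  The hub is the gene with the largest summed correlation to
    the others (ties broken by lexicographic gene id) and the module keeps
    genes whose correlation with the hub is at least ``corr_threshold``.
    Types whose surviving module has fewer than ``min_module_size`` genes
    are omitted from the result — undetectable in this dataset.
    """
    if not 0 < corr_threshold < 1:
        raise ValidationError("corr_threshold must lie in (0, 1)")
    if min_module_size < 2:
        raise ValidationError("min_module_size must be >= 2")
    modules: list[MarkerModule] = []
    for k, type_name in enumerate(labeling.type_names):
        labeled = [
            g
            for g, v in zip(labeling.gene_ids, labeling.values[:, k])
            if v > 0 and X.has_gene(g)
        ]
        usable = []
        for g in labeled:
            if np.ptp(X.gene_row(g)) == 0:
                logger.warning(
                    "gene %r has constant expression; excluded from module "
                    "detection for type %r",
                    g,
                    type_name,
                )
                continue
            usable.append(g)
        if len(usable) < min_module_size:
            logger.warning(
                "type %r undetectable: %d usable labeled genes < %d",
                type_name,
                len(usable),
                min_module_size,
            )
            continue
        sub = np.vstack([X.gene_row(g) for g in usable])
        rho = stats.spearmanr(sub, axis=1).statistic
        rho = np.atleast_2d(np.asarray(rho, dtype=float))
        np.fill_diagonal(rho, 1.0)
        summed = rho.sum(axis=1) - 1.0  # exclude self-correlation
        # ties broken lexicographically for determinism
        order = sorted(range(len(usable)), key=lambda i: (-summed[i], usable[i]))
        hub_i = order[0]
        member_idx = [
            i for i in range(len(usable)) if rho[hub_i, i] >= corr_threshold
        ]
        members = [usable[i] for i in member_idx]
        if len(members) < min_module_size:
            logger.warning(
                "type %r undetectable: module of size %d < %d after filtering",
                type_name,
                len(members),
                min_module_size,
            )
            continue
        mm = rho[np.ix_(member_idx, member_idx)]
        iu = np.triu_indices(len(member_idx), k=1)
        mean_corr = float(mm[iu].mean()) if len(iu[0]) else 1.0
        modules.append(
            MarkerModule(
                type_name=type_name,
                hub_gene=usable[hub_i],
                member_genes=members,
                mean_internal_correlation=mean_corr,
            )
        )
    return modules
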