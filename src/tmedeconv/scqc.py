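"""Single-cell validation: QC filtering, normalization, FFM assignment.

Droplet barcodes are filtered on four criteria, all strict inequalities:
total UMIs above 400, expressed genes above 200 and below 6000, and
mitochondrial fraction (UMIs on ``MT-``-prefixed genes over total UMIs)
below 25%.  Boundary cells — exactly 400 UMIs, exactly 6000 genes,
exactly 25% mitochondrial — fail.

Surviving cells are normalized by library-size scaling to 10,000 counts
followed by ``ln(1 + x)``, the standard single-cell toolkit default.
Per-cell fibroblast functional-module (FFM) scores are mean normalized
expression of each module's markers; a Welch two-sided t-test compares
fibroblasts against all other cell types per module, and fibroblasts are
assigned to the subgroup with the highest score — or to "Others" when no
module's markers are expressed (max score not above ``min_score``) or the
top scores tie (ambiguous evidence).

Clustering, principal components and cell-type annotation are not
re-implemented here: cell-type labels arrive as input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy import stats as sps

from .containers import MarkerSet, ValidationError, normalize_gene_id

__all__ = [
    "CellQCRecord",
    "CellFFMAssignment",
    "qc_filter",
    "normalize_counts",
    "score_ffm_per_cell",
    "test_fibroblast_enrichment",
    "assign_ffm_subgroup",
]

logger = logging.getLogger(__name__)

FFM_LABELS = ("FFM1", "FFM2", "FFM3", "FFM4")


@dataclass
class CellQCRecord:
    """Quality metrics and filter outcome for one barcode."""

    barcode: str
    umi_total: int
    n_genes: int
    mito_fraction: float
    passed: bool
    fail_reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.fail_reasons) == 0):
            raise ValidationError("passed flag inconsistent with fail_reasons")


@dataclass
class CellFFMAssignment:
    """FFM subgroup call for one fibroblast."""

    barcode: str
    cell_type: str
    ffm_scores: np.ndarray
    subgroup: str  # FFM1..FFM4 or Others


def qc_filter(
    counts: sp.spmatrix,
    barcodes: Sequence[str],
    genes: Sequence[str],
    min_umi: int = 400,
    min_genes: int = 200,
    max_genes: int = 6000,
    max_mito: float = 0.25,
    mito_prefix: str = "MT-",
) -> tuple[sp.csr_matrix, list[str], list[CellQCRecord]]:
    """Filter a cells x genes count matrix on the four QC criteria.

    A cell is kept iff ``umi_total > min_umi``, ``min_genes < n_genes <
    max_genes`` and ``mito_fraction < max_mito`` — all strict.  Every cell
    receives a :class:`CellQCRecord` listing all applicable failure
    reasons.  Returns ``(filtered counts, kept barcodes, records)``.
    """
    counts = sp.csr_matrix(counts)
    if counts.shape[0] != len(barcodes) or counts.shape[1] != len(genes):
        raise ValidationError("counts shape does not match barcode/gene lists")
    prefix = normalize_gene_id(mito_prefix)
    mito_cols = np.array(
        [normalize_gene_id(g).startswith(prefix) for g in genes], dtype=bool
    )
    umi = np.asarray(counts.sum(axis=1)).ravel()
    n_genes_per_cell = np.asarray((counts > 0).sum(axis=1)).ravel()
    if mito_cols.any():
        mito_counts = np.asarray(counts[:, mito_cols].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(umi > 0, mito_counts / np.maximum(umi, 1), 0.0)
    else:
        logger.warning(
            "no genes match mitochondrial prefix %r; mito_fraction set to 0",
            mito_prefix,
        )
        mito_frac = np.zeros(counts.shape[0])
    records = []
    keep = np.zeros(counts.shape[0], dtype=bool)
    for i, bc in enumerate(barcodes):
        reasons = []
        if not umi[i] > min_umi:
            reasons.append("low_umi")
        if not n_genes_per_cell[i] > min_genes:
            reasons.append("low_genes")
        if not n_genes_per_cell[i] < max_genes:
            reasons.append("high_genes")
        if not mito_frac[i] < max_mito:
            reasons.append("high_mito")
        keep[i] = not reasons
        records.append(
            CellQCRecord(
                barcode=str(bc),
                umi_total=int(umi[i]),
                n_genes=int(n_genes_per_cell[i]),
                mito_fraction=float(mito_frac[i]),
                passed=not reasons,
                fail_reasons=tuple(reasons),
            )
        )
    kept_barcodes = [str(b) for b, k in zip(barcodes, keep) if k]
    return counts[keep], kept_barcodes, records


def normalize_counts(counts: sp.spmatrix, target_sum: float = 1e4) -> sp.csr_matrix:
    """Library-size normalize to ``target_sum`` per cell, then ``ln(1+x)``."""
    counts = sp.csr_matrix(counts, dtype=float)
    lib = np.asarray(counts.sum(axis=1)).ravel()
    if np.any(lib == 0):
        raise ValidationError("zero-count cell encountered; run qc_filter first")
    scaled = sp.diags(target_sum / lib) @ counts
    scaled.data = np.log1p(scaled.data)
    return scaled.tocsr()


def score_ffm_per_cell(
    normalized: sp.spmatrix,
    genes: Sequence[str],
    ffm_sets: Sequence[MarkerSet],
) -> np.ndarray:
    """Mean normalized expression of each module's markers, per cell.

    Returns an array of shape ``(n_cells, len(ffm_sets))`` in the order of
    ``ffm_sets``.
    """
    normalized = sp.csr_matrix(normalized)
    index = {normalize_gene_id(g): j for j, g in enumerate(genes)}
    scores = np.zeros((normalized.shape[0], len(ffm_sets)))
    for k, ms in enumerate(ffm_sets):
        cols = [index[normalize_gene_id(g)] for g in ms.genes
                if normalize_gene_id(g) in index]
        if not cols:
            raise ValidationError(f"no genes of module {ms.name!r} in the matrix")
        scores[:, k] = np.asarray(normalized[:, cols].mean(axis=1)).ravel()
    return scores


def test_fibroblast_enrichment(
    scores: np.ndarray,
    cell_type_labels: Sequence[str],
    fibroblast_label: str = "fibroblast",
    ffm_names: Sequence[str] = FFM_LABELS,
) -> list[tuple[str, float, float]]:
    """Welch t-test of fibroblasts vs all other cells, per FFM score.

    Returns ``[(ffm_name, t_statistic, two_sided_p), ...]``.
    """
    labels = np.asarray([str(c) for c in cell_type_labels])
    is_fib = labels == fibroblast_label
    if is_fib.sum() < 2 or (~is_fib).sum() < 2:
        raise ValidationError("need >= 2 fibroblasts and >= 2 other cells")
    out = []
    for k, name in enumerate(ffm_names):
        res = sps.ttest_ind(
            scores[is_fib, k], scores[~is_fib, k], equal_var=False
        )
        out.append((str(name), float(res.statistic), float(res.pvalue)))
    return out


def assign_ffm_subgroup(
    scores: np.ndarray,
    barcodes: Sequence[str],
    min_score: float = 0.0,
    cell_type: str = "fibroblast",
    ffm_names: Sequence[str] = FFM_LABELS,
) -> list[CellFFMAssignment]:
    """Assign each fibroblast to the argmax FFM subgroup, or to "Others".

    A cell goes to "Others" when its best score does not exceed
    ``min_score`` (no marker expression) or when the top score is tied
    between modules (ambiguous evidence).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != len(barcodes) or scores.shape[1] != len(ffm_names):
        raise ValidationError("scores shape does not match barcodes/modules")
    out = []
    for i, bc in enumerate(barcodes):
        row = scores[i]
        best = float(row.max())
        if best <= min_score or np.sum(row == best) > 1:
            subgroup = "Others"
        else:
            subgroup = str(ffm_names[int(np.argmax(row))])
        out.append(
            CellFFMAssignment(
                barcode=str(bc),
                cell_type=cell_type,
                ffm_scores=row.copy(),
                subgroup=subgroup,
            )
        )
    return out
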