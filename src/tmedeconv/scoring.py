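"""Per-sample summary statistics: FFM activities and T-cell cytotoxicity.

Fibroblast functional-module (FFM) activity is the arithmetic mean of the
``log2(x + 1)``-transformed expression of the module's marker genes in
each sample.  Averaging on the log scale stops a single highly expressed
collagen from dominating the module; the transform is applied by the
scoring functions themselves, so the input matrix stays linear-scale.

Relative T-cell cytotoxicity is the log2 ratio of mean cytotoxic-effector
marker expression (perforin 1, granzyme A by default) to mean pan-T-cell
marker expression (CD2 and CD3D by default; "CD3" is a receptor complex,
so a concrete subunit symbol is used).  A pseudocount guards zero
denominators: it is added to both numerator and denominator only when one
of the two means is zero, which keeps the score exactly invariant to a
common scaling of all four genes whenever both means are positive.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MarkerSet, SampleMetadata, ValidationError

__all__ = [
    "ffm_activity",
    "relative_cytotoxicity",
    "build_activity_table",
    "DEFAULT_CYTOTOXIC_GENES",
    "DEFAULT_TCELL_GENES",
]

DEFAULT_CYTOTOXIC_GENES = ("PRF1", "GZMA")
DEFAULT_TCELL_GENES = ("CD2", "CD3D")


def ffm_activity(
    X: ExpressionMatrix, ffm_sets: Sequence[MarkerSet]
) -> pd.DataFrame:
    """Mean log2(x+1) marker expression per sample, one column per module.

    Raises if any module has no genes present in ``X``.
    """
    L = X.log2_values()
    cols = {}
    for ms in ffm_sets:
        idx = X.gene_indices(ms.genes)
        if not idx:
            raise ValidationError(f"no genes of module {ms.name!r} present in X")
        cols[ms.name] = L[idx, :].mean(axis=0)
    return pd.DataFrame(cols, index=pd.Index(X.sample_ids, name="sample_id"))


def relative_cytotoxicity(
    X: ExpressionMatrix,
    cytotoxic_genes: Sequence[str] = DEFAULT_CYTOTOXIC_GENES,
    tcell_genes: Sequence[str] = DEFAULT_TCELL_GENES,
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2 ratio of cytotoxic-marker mean to T-cell-marker mean, per sample."""
    cyt_idx = X.gene_indices(cytotoxic_genes)
    tc_idx = X.gene_indices(tcell_genes)
    if not cyt_idx and not tc_idx:
        raise ValidationError(
            "neither cytotoxic nor T-cell marker genes present in X"
        )
    if not cyt_idx:
        raise ValidationError(f"no cytotoxic genes {list(cytotoxic_genes)} in X")
    if not tc_idx:
        raise ValidationError(f"no T-cell genes {list(tcell_genes)} in X")
    cyt = X.values[cyt_idx, :].mean(axis=0)
    tc = X.values[tc_idx, :].mean(axis=0)
    need_eps = (cyt == 0) | (tc == 0)
    num = np.where(need_eps, cyt + pseudocount, cyt)
    den = np.where(need_eps, tc + pseudocount, tc)
    # sign-stable form: the magnitude is computed from the larger/smaller
    # ratio, so swapping the two gene groups negates the score exactly and
    # a common scale factor cancels exactly
    big = np.maximum(num, den)
    small = np.minimum(num, den)
    mag = np.log2(big / small)
    score = np.where(num >= den, mag, -mag)
    score[num == den] = 0.0
    return pd.Series(
        score, index=pd.Index(X.sample_ids, name="sample_id"), name="cytotoxicity"
    )


def build_activity_table(
    X: ExpressionMatrix,
    ffm_sets: Sequence[MarkerSet],
    immune_proportions: pd.DataFrame | None = None,
    metadata: SampleMetadata | None = None,
    cytotoxic_genes: Sequence[str] = DEFAULT_CYTOTOXIC_GENES,
    tcell_genes: Sequence[str] = DEFAULT_TCELL_GENES,
    include_cytotoxicity: bool = True,
) -> pd.DataFrame:
    """Assemble the per-sample activity table used by all downstream statistics.

    Columns: one per FFM module, optional immune-cell proportions (joined
    on sample id), the cytotoxicity score, and ``group``/``disease_score``
    from metadata when provided.
    """
    table = ffm_activity(X, ffm_sets)
    if immune_proportions is not None:
        table = table.join(immune_proportions, how="left")
    if include_cytotoxicity:
        try:
            table["cytotoxicity"] = relative_cytotoxicity(
                X, cytotoxic_genes, tcell_genes
            )
        except ValidationError:
            pass  # cytotoxicity genes absent: leave the column out
    if metadata is not None:
        meta = metadata.aligned_to(list(table.index))
        table["group"] = meta.group
        if meta.disease_score is not None:
            table["disease_score"] = meta.disease_score
    return table
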