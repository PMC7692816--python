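"""Core in-memory containers shared by every pipeline stage.

The pipeline works on three kinds of objects: a non-negative gene-by-sample
expression matrix, named marker-gene sets (cell types and fibroblast
functional modules), and per-sample metadata (group labels and an optional
disease score, the percentage of malignant cells in a specimen).

Gene identifiers are matched case-insensitively after trimming whitespace
throughout the package; mapping between mouse and human symbols is the
caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "MarkerSet",
    "SampleMetadata",
    "normalize_gene_id",
]


class ValidationError(ValueError):
    """Raised when an input object violates a container invariant."""


def normalize_gene_id(gene: str) -> str:
    """Canonical form used for gene matching: trimmed, upper-cased."""
    return gene.strip().upper()


def _find_duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass
class ExpressionMatrix:
    """A genes x samples abundance table.

    Values are linear-scale and non-negative unless ``log_flag`` is set, in
    which case they are understood to be log-transformed and may be negative.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (rows).
    sample_ids
        Ordered, unique sample identifiers (columns).
    values
        Array of shape ``(len(gene_ids), len(sample_ids))``; all finite.
    log_flag
        Whether ``values`` are already log-transformed.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    log_flag: bool = False
    _gene_index: dict[str, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup_g = _find_duplicates([normalize_gene_id(g) for g in self.gene_ids])
        if dup_g:
            raise ValidationError(f"duplicate gene identifiers: {dup_g}")
        dup_s = _find_duplicates(self.sample_ids)
        if dup_s:
            raise ValidationError(f"duplicate sample identifiers: {dup_s}")
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if not self.log_flag and np.any(self.values < 0):
            g, s = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative value {self.values[g, s]} at gene "
                f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r} "
                "(log_flag is false)"
            )
        self._gene_index = {
            normalize_gene_id(g): i for i, g in enumerate(self.gene_ids)
        }

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        """Expression of one gene across samples (case-insensitive lookup)."""
        idx = self._gene_index.get(normalize_gene_id(gene))
        if idx is None:
            raise KeyError(f"gene {gene!r} not present")
        return self.values[idx]

    def has_gene(self, gene: str) -> bool:
        return normalize_gene_id(gene) in self._gene_index

    def gene_indices(self, genes: Iterable[str]) -> list[int]:
        """Indices of the genes present in this matrix, input order kept."""
        out = []
        for g in genes:
            idx = self._gene_index.get(normalize_gene_id(g))
            if idx is not None:
                out.append(idx)
        return out

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_indices(genes)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx, :].copy(),
            log_flag=self.log_flag,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, log_flag: bool = False) -> "ExpressionMatrix":
        return cls(
            list(map(str, frame.index)),
            list(map(str, frame.columns)),
            frame.to_numpy(dtype=float),
            log_flag=log_flag,
        )

    def log2_values(self) -> np.ndarray:
        """``log2(x + 1)`` of the linear values (identity if already log)."""
        if self.log_flag:
            return self.values
        return np.log2(self.values + 1.0)


@dataclass(frozen=True)
class MarkerSet:
    """A named, ordered list of marker genes for one cell type or module."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ValidationError("marker set name must be non-empty")
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))
        if len(self.genes) == 0:
            raise ValidationError(f"marker set {self.name!r} has no genes")
        dups = _find_duplicates([normalize_gene_id(g) for g in self.genes])
        if dups:
            raise ValidationError(
                f"duplicate genes in marker set {self.name!r}: {dups}"
            )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SampleMetadata:
    """Per-sample annotations: group label and optional disease score.

    The disease score is the percentage of malignant cells in the tissue
    specimen (0-100); it must be present for all samples or for none.
    """

    sample_ids: list[str]
    group: list[str]
    disease_score: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.group = [str(g) for g in self.group]
        if len(self.group) != len(self.sample_ids):
            raise ValidationError("group labels must match sample_ids length")
        dups = _find_duplicates(self.sample_ids)
        if dups:
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        if self.disease_score is not None:
            self.disease_score = np.asarray(self.disease_score, dtype=float)
            if self.disease_score.shape != (len(self.sample_ids),):
                raise ValidationError(
                    "disease_score must have one value per sample (or be absent)"
                )
            if np.any(np.isnan(self.disease_score)):
                raise ValidationError(
                    "disease_score must be present for all samples or none"
                )
            if np.any((self.disease_score < 0) | (self.disease_score > 100)):
                raise ValidationError("disease_score values must lie in [0, 100]")

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.group) if g == label]

    def group_mask(self, label: str) -> np.ndarray:
        return np.array([g == label for g in self.group], dtype=bool)

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        """Reorder metadata to match an expression matrix's sample order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        idx = [pos[s] for s in sample_ids]
        return SampleMetadata(
            [self.sample_ids[i] for i in idx],
            [self.group[i] for i in idx],
            None if self.disease_score is None else self.disease_score[idx],
        )


def marker_sets_as_mapping(sets: Iterable[MarkerSet]) -> Mapping[str, tuple[str, ...]]:
    return {m.name: m.genes for m in sets}
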