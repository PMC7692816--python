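"""Readers and writers for expression tables, marker sets and metadata.

Supported on-disk formats
-------------------------
* TSV/CSV expression tables: header row of sample ids, first column of gene
  ids, genes in rows (``samples_in_rows=True`` transposes on read).
* Matrix Market coordinate (triplet) files with sidecar ``genes.tsv`` and
  ``barcodes.tsv`` name files, used both for sparse single-cell counts and
  as an alternative bulk format.
* Marker sets as two-column TSV (``set_name<TAB>gene``), one row per gene,
  file order preserved.
* Sample metadata as TSV with columns ``sample_id``, ``group`` and an
  optional ``disease_score``.
* YAML configuration files.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .containers import (
    ExpressionMatrix,
    MarkerSet,
    SampleMetadata,
    ValidationError,
    normalize_gene_id,
)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_marker_sets",
    "write_marker_sets",
    "default_ffm_marker_sets",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_sc_counts",
    "write_sc_counts",
    "load_config",
]


def _read_name_file(path: Path) -> list[str]:
    # first column of a headerless TSV (10x-style sidecar)
    names = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                names.append(line.split("\t")[0])
    return names


def read_expression_matrix(
    path: str | os.PathLike,
    format: str = "tsv",
    log_flag: bool = False,
    samples_in_rows: bool = False,
) -> ExpressionMatrix:
    """Read an expression table into an :class:`ExpressionMatrix`.

    ``format`` is one of ``tsv``, ``csv`` or ``mtx_triplet``.  For
    ``mtx_triplet`` the files ``genes.tsv`` and ``barcodes.tsv`` must sit
    next to the ``.mtx`` file; the matrix is densified (genes in rows).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        # round_trip parsing so write->read is bit-exact
        frame = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        if samples_in_rows:
            frame = frame.T
    elif format == "mtx_triplet":
        genes_file = path.parent / "genes.tsv"
        barcodes_file = path.parent / "barcodes.tsv"
        for side in (genes_file, barcodes_file):
            if not side.exists():
                raise FileNotFoundError(f"missing sidecar name file: {side}")
        mat = sp.coo_matrix(scipy.io.mmread(path))
        genes = _read_name_file(genes_file)
        samples = _read_name_file(barcodes_file)
        if mat.shape != (len(genes), len(samples)):
            raise ValidationError(
                f"matrix shape {mat.shape} does not match sidecar files "
                f"({len(genes)} genes, {len(samples)} columns)"
            )
        frame = pd.DataFrame(mat.toarray(), index=genes, columns=samples)
        if samples_in_rows:
            frame = frame.T
    else:
        raise ValueError(f"unknown format {format!r}")
    return ExpressionMatrix.from_frame(frame, log_flag=log_flag)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | os.PathLike, format: str = "tsv"
) -> None:
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        # default float repr is shortest-round-trip: read(write(x)) == x
        matrix.to_frame().to_csv(path, sep=sep)
    elif format == "mtx_triplet":
        scipy.io.mmwrite(str(path), sp.coo_matrix(matrix.values))
        (path.parent / "genes.tsv").write_text(
            "\n".join(matrix.gene_ids) + "\n"
        )
        (path.parent / "barcodes.tsv").write_text(
            "\n".join(matrix.sample_ids) + "\n"
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_marker_sets(path: str | os.PathLike) -> list[MarkerSet]:
    """Read two-column ``set_name<TAB>gene`` marker files.

    One :class:`MarkerSet` per distinct set name, in file order.  A gene
    repeated within one set, or an empty set name, is an error.
    """
    path = Path(path)
    order: list[str] = []
    genes: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(
                    f"{path.name}:{lineno}: expected 'set_name<TAB>gene'"
                )
            name, gene = parts[0].strip(), parts[1].strip()
            if lineno == 1 and name.lower() in ("set_name", "set", "module"):
                continue  # optional header
            if not name:
                raise ValidationError(f"{path.name}:{lineno}: empty set name")
            if not gene:
                raise ValidationError(f"{path.name}:{lineno}: empty gene id")
            if name not in genes:
                order.append(name)
                genes[name] = []
            if normalize_gene_id(gene) in {
                normalize_gene_id(g) for g in genes[name]
            }:
                raise ValidationError(
                    f"gene {gene!r} repeated within marker set {name!r}"
                )
            genes[name].append(gene)
    return [MarkerSet(name, tuple(genes[name])) for name in order]


def write_marker_sets(sets: Sequence[MarkerSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("set_name\tgene\n")
        for ms in sets:
            for g in ms.genes:
                fh.write(f"{ms.name}\t{g}\n")


def default_ffm_marker_sets() -> list[MarkerSet]:
    """The packaged fibroblast functional-module marker sets (FFM1-4).

    FFM1 carries non-collagen stromal markers; FFM2 the collagen 1/3/5
    family; FFM3 collagen 4; FFM4 collagen 6.
    """
    from importlib.resources import files

    return read_marker_sets(str(files("tmedeconv.data") / "ffm_markers.tsv"))


def read_sample_metadata(path: str | os.PathLike) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group"}
    if not required.issubset(frame.columns):
        raise ValidationError(
            f"metadata file must have columns {sorted(required)}"
        )
    score = None
    if "disease_score" in frame.columns:
        score = frame["disease_score"].to_numpy(dtype=float)
    return SampleMetadata(
        list(frame["sample_id"].astype(str)),
        list(frame["group"].astype(str)),
        score,
    )


def write_sample_metadata(meta: SampleMetadata, path: str | os.PathLike) -> None:
    data = {"sample_id": meta.sample_ids, "group": meta.group}
    if meta.disease_score is not None:
        data["disease_score"] = meta.disease_score
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_sc_counts(
    mtx_path: str | os.PathLike,
) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Read a sparse single-cell count matrix.

    The ``.mtx`` file stores genes in rows and cell barcodes in columns
    (the common droplet-platform convention) with sidecar ``genes.tsv`` and
    ``barcodes.tsv``.  Returns a cells x genes CSR matrix plus the gene and
    barcode name lists.
    """
    mtx_path = Path(mtx_path)
    genes = _read_name_file(mtx_path.parent / "genes.tsv")
    barcodes = _read_name_file(mtx_path.parent / "barcodes.tsv")
    mat = sp.csr_matrix(scipy.io.mmread(mtx_path)).T.tocsr()
    if mat.shape != (len(barcodes), len(genes)):
        raise ValidationError(
            f"count matrix shape {mat.shape} does not match sidecars "
            f"({len(barcodes)} barcodes, {len(genes)} genes)"
        )
    return mat, genes, barcodes


def write_sc_counts(
    counts: sp.spmatrix,
    genes: Sequence[str],
    barcodes: Sequence[str],
    out_dir: str | os.PathLike,
    mtx_name: str = "matrix.mtx",
) -> Path:
    """Write cells x genes counts as genes-in-rows ``.mtx`` plus sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mtx_path = out_dir / mtx_name
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(counts.T))
    (out_dir / "genes.tsv").write_text("\n".join(genes) + "\n")
    (out_dir / "barcodes.tsv").write_text("\n".join(barcodes) + "\n")
    return mtx_path


def load_config(path: str | os.PathLike | None) -> dict:
    """Load a YAML configuration file; ``None`` gives an empty config."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
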