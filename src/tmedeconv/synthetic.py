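"""Synthetic data with known ground truth for every pipeline stage.

Bulk tissue is emulated as convex mixtures of cell-type signatures: sample
proportions are drawn from a Dirichlet (columns sum to one), the noiseless
expression is the matrix product of signature and proportion, and noise is
multiplicative log-normal so values stay non-negative and heteroskedastic,
as real expression noise is.  Immune genes whose expression tracks a chosen
cell type are appended as monotone (exponential) transforms of that type's
standardized proportion.  Single-cell UMI counts are drawn per-gene Poisson
with rates scaled to a log-normal per-cell library size; fibroblasts
express the marker genes of their assigned functional-module subgroup at an
elevated rate, and mitochondrial genes carry the ``MT-`` prefix so the
quality-control stage can find them.

None of this attempts to match real ovarian-cancer expression
distributions, batch effects or dropout curves; the generators exist to
give every downstream estimator a ground truth it can be scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .containers import ExpressionMatrix, MarkerSet, ValidationError

__all__ = [
    "SyntheticTruth",
    "SyntheticSCTruth",
    "generate_signatures",
    "generate_mixture",
    "inject_coupled_genes",
    "generate_sc_counts",
    "qc_boundary_fixture",
]

SC_CELL_TYPES = (
    "fibroblast",
    "endothelial",
    "epithelial",
    "erythroid",
    "B",
    "myeloid",
    "T",
)
FFM_SUBGROUPS = ("FFM1", "FFM2", "FFM3", "FFM4", "Others")


@dataclass
class SyntheticTruth:
    """Hidden parameters behind a simulated bulk mixture."""

    S_true: np.ndarray  # genes x types
    P_true: np.ndarray  # types x samples, columns sum to 1
    type_names: list[str]
    marker_map: list[MarkerSet]
    coupling: list[tuple[str, str, float]] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class SyntheticSCTruth:
    """Hidden per-barcode labels and QC covariates of simulated cells."""

    barcodes: list[str]
    cell_labels: list[str]
    ffm_labels: list[str | None]  # None for non-fibroblasts
    umi_totals: np.ndarray
    gene_counts: np.ndarray
    mito_fractions: np.ndarray
    ffm_marker_sets: list[MarkerSet] = field(default_factory=list)
    seed: int = 0


def generate_signatures(
    n_genes: int,
    type_names: Sequence[str],
    markers_per_type: int = 5,
    marker_fold: float = 10.0,
    base_level: float = 100.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[MarkerSet]]:
    """Build a genes x types signature matrix with planted marker genes.

    The first ``len(type_names) * markers_per_type`` genes are markers: a
    marker's expected signature is ``base_level * marker_fold`` in its own
    type and ``base_level`` elsewhere.  Non-marker genes share a common
    (gene-specific) level across all types.  Gene-specific baselines are
    drawn uniformly in ``[0.5, 1.5] * base_level`` so rows are not
    identical; expectations match the construction above.
    """
    type_names = list(type_names)
    if marker_fold <= 1.0:
        raise ValidationError("marker_fold must exceed 1 (markers must stand out)")
    if markers_per_type < 1 or n_genes < len(type_names) * markers_per_type:
        raise ValidationError(
            f"gene budget infeasible: need {len(type_names) * markers_per_type} "
            f"marker genes but n_genes={n_genes}"
        )
    rng = np.random.default_rng(seed)
    base = base_level * rng.uniform(0.5, 1.5, size=n_genes)
    S = np.tile(base[:, None], (1, len(type_names)))
    marker_sets = []
    g = 0
    for k, name in enumerate(type_names):
        genes = []
        for _ in range(markers_per_type):
            S[g, k] = base[g] * marker_fold
            genes.append(f"MK_{name}_{g:04d}")
            g += 1
        marker_sets.append(MarkerSet(name, tuple(genes)))
    return S, marker_sets


def _gene_names(marker_sets: Sequence[MarkerSet], n_genes: int) -> list[str]:
    names = [g for ms in marker_sets for g in ms.genes]
    names += [f"G{j:05d}" for j in range(len(names), n_genes)]
    return names


def generate_mixture(
    S_true: np.ndarray,
    n_samples: int,
    dirichlet_alpha: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    type_names: Sequence[str] | None = None,
    marker_sets: Sequence[MarkerSet] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Mix signatures into bulk samples with multiplicative log-normal noise.

    Proportion columns are Dirichlet(``dirichlet_alpha``) draws; the
    observed matrix is ``(S_true @ P_true) * exp(eps)`` with
    ``eps ~ Normal(0, noise_sd^2)`` i.i.d.  ``noise_sd = 0`` returns the
    exact product.
    """
    S_true = np.asarray(S_true, dtype=float)
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    n_types = S_true.shape[1]
    if alpha.shape != (n_types,):
        raise ValidationError(
            f"alpha length {alpha.shape} does not match {n_types} types"
        )
    rng = np.random.default_rng(seed)
    P = rng.dirichlet(alpha, size=n_samples).T  # types x samples
    X = S_true @ P
    if noise_sd > 0:
        X = X * np.exp(rng.normal(0.0, noise_sd, size=X.shape))
    if type_names is None:
        type_names = (
            [ms.name for ms in marker_sets]
            if marker_sets is not None
            else [f"type{k + 1}" for k in range(n_types)]
        )
    marker_sets = list(marker_sets) if marker_sets is not None else []
    gene_ids = _gene_names(marker_sets, S_true.shape[0])
    sample_ids = [f"S{j + 1:04d}" for j in range(n_samples)]
    matrix = ExpressionMatrix(gene_ids, sample_ids, X)
    truth = SyntheticTruth(
        S_true=S_true,
        P_true=P,
        type_names=list(type_names),
        marker_map=marker_sets,
        noise_sd=noise_sd,
        seed=seed,
    )
    return matrix, truth


def inject_coupled_genes(
    X: ExpressionMatrix,
    truth: SyntheticTruth,
    couplings: Sequence[tuple[str, str, float]],
    noise_sd: float = 0.1,
    seed: int = 0,
    scale: float = 100.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Append genes whose expression co-varies with a cell type's proportion.

    Each appended gene takes values
    ``scale * exp(beta * zscore(P_true[target, :]) + eps)`` with
    ``eps ~ Normal(0, noise_sd^2)``: on the log scale the gene is a linear
    function of the standardized target proportion, so the sign of ``beta``
    sets the sign of the expected (rank) correlation with that proportion.
    Returns a new matrix with the genes appended and an updated truth
    carrying the coupling list.
    """
    rng = np.random.default_rng(seed)
    name_to_row = {t: i for i, t in enumerate(truth.type_names)}
    new_rows = []
    new_names = []
    for gene, target, beta in couplings:
        if X.has_gene(gene) or gene in new_names:
            raise ValidationError(f"gene {gene!r} already present")
        if target not in name_to_row:
            raise ValidationError(f"unknown target type {target!r}")
        p = truth.P_true[name_to_row[target], :]
        sd = p.std()
        z = (p - p.mean()) / sd if sd > 0 else np.zeros_like(p)
        eps = rng.normal(0.0, noise_sd, size=p.shape) if noise_sd > 0 else 0.0
        new_rows.append(scale * np.exp(beta * z + eps))
        new_names.append(gene)
    out = ExpressionMatrix(
        X.gene_ids + new_names,
        list(X.sample_ids),
        np.vstack([X.values] + [r[None, :] for r in new_rows])
        if new_rows
        else X.values.copy(),
        log_flag=X.log_flag,
    )
    new_truth = SyntheticTruth(
        S_true=truth.S_true,
        P_true=truth.P_true,
        type_names=list(truth.type_names),
        marker_map=list(truth.marker_map),
        coupling=list(truth.coupling) + [tuple(c) for c in couplings],
        noise_sd=truth.noise_sd,
        seed=truth.seed,
    )
    return out, new_truth


def generate_sc_counts(
    n_cells_per_type: Mapping[str, int],
    ffm_mix: Mapping[str, float] | None = None,
    mean_umi: float = 2000.0,
    mito_mean: float = 0.05,
    seed: int = 0,
    markers_per_ffm: int = 20,
    marker_fold: float = 5.0,
    n_background_genes: int = 400,
    n_mito_genes: int = 10,
    umi_sigma: float = 0.5,
) -> tuple[sp.csr_matrix, list[str], list[str], SyntheticSCTruth]:
    """Simulate a sparse UMI count matrix with labelled cells.

    Per-cell library sizes are log-normal with mean ``mean_umi``
    (log-scale sd ``umi_sigma``); gene counts are Poisson with rates
    proportional to the cell's expression profile scaled to its library
    size.  Fibroblasts are split across functional-module subgroups per
    ``ffm_mix`` (default: uniform over FFM1-4); a fibroblast expresses its
    own subgroup's markers at ``marker_fold`` times the background rate,
    while "Others" fibroblasts express none of the four marker sets above
    background.  Mitochondrial genes (prefix ``MT-``) receive an expected
    ``mito_mean`` fraction of each cell's counts.

    Returns ``(counts, genes, barcodes, truth)`` with counts cells x genes.
    """
    if ffm_mix is None:
        ffm_mix = {"FFM1": 0.25, "FFM2": 0.25, "FFM3": 0.25, "FFM4": 0.25}
    mix_labels = list(ffm_mix)
    mix_probs = np.array([ffm_mix[k] for k in mix_labels], dtype=float)
    if not np.isclose(mix_probs.sum(), 1.0):
        raise ValidationError("ffm_mix proportions must sum to 1")
    for lab in mix_labels:
        if lab not in FFM_SUBGROUPS:
            raise ValidationError(f"unknown FFM subgroup {lab!r}")
    if not 0.0 <= mito_mean <= 1.0:
        raise ValidationError("mito_mean must lie in [0, 1]")
    unknown = [t for t in n_cells_per_type if t not in SC_CELL_TYPES]
    if unknown:
        raise ValidationError(f"unknown cell types: {unknown}")

    rng = np.random.default_rng(seed)

    ffm_names = ("FFM1", "FFM2", "FFM3", "FFM4")
    ffm_sets = [
        MarkerSet(
            name,
            tuple(f"{name}_M{j:03d}" for j in range(markers_per_ffm)),
        )
        for name in ffm_names
    ]
    mito_genes = [f"MT-{j + 1}" for j in range(n_mito_genes)]
    bg_genes = [f"BG{j:04d}" for j in range(n_background_genes)]
    genes = [g for ms in ffm_sets for g in ms.genes] + mito_genes + bg_genes
    n_genes = len(genes)
    ffm_idx = {
        ms.name: np.arange(i * markers_per_ffm, (i + 1) * markers_per_ffm)
        for i, ms in enumerate(ffm_sets)
    }
    n_ffm_genes = 4 * markers_per_ffm
    mito_idx = np.arange(n_ffm_genes, n_ffm_genes + n_mito_genes)
    bg_idx = np.arange(n_ffm_genes + n_mito_genes, n_genes)

    cell_labels: list[str] = []
    ffm_labels: list[str | None] = []
    for ctype in SC_CELL_TYPES:
        n = int(n_cells_per_type.get(ctype, 0))
        for _ in range(n):
            cell_labels.append(ctype)
            if ctype == "fibroblast":
                ffm_labels.append(
                    mix_labels[rng.choice(len(mix_labels), p=mix_probs)]
                )
            else:
                ffm_labels.append(None)
    n_cells = len(cell_labels)
    if n_cells == 0:
        raise ValidationError("no cells requested")
    barcodes = [f"CELL{j + 1:05d}" for j in range(n_cells)]

    # log-normal library sizes with mean == mean_umi
    mu = np.log(mean_umi) - 0.5 * umi_sigma**2
    libsizes = rng.lognormal(mu, umi_sigma, size=n_cells)

    rows, cols, data = [], [], []
    for c in range(n_cells):
        rate = np.ones(n_genes)
        rate[mito_idx] = 0.0
        sub = ffm_labels[c]
        all_ffm = np.concatenate([ffm_idx[n] for n in ffm_names])
        if sub is not None and sub != "Others":
            rate[ffm_idx[sub]] = marker_fold
        elif sub == "Others":
            # "Others" fibroblasts express none of the four marker panels
            rate[all_ffm] = 0.0
        else:
            # non-fibroblasts: low background on the FFM panels
            rate[all_ffm] = 0.2
        rate = rate / rate.sum() * (1.0 - mito_mean)
        if n_mito_genes:
            rate[mito_idx] = mito_mean / n_mito_genes
        counts_c = rng.poisson(libsizes[c] * rate)
        nz = np.nonzero(counts_c)[0]
        rows.extend([c] * len(nz))
        cols.extend(nz.tolist())
        data.extend(counts_c[nz].tolist())
    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(n_cells, n_genes), dtype=np.int64
    )

    umi_totals = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    gene_counts = np.asarray((counts > 0).sum(axis=1)).ravel().astype(float)
    mito_counts = np.asarray(counts[:, mito_idx].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fractions = np.where(umi_totals > 0, mito_counts / umi_totals, 0.0)

    truth = SyntheticSCTruth(
        barcodes=barcodes,
        cell_labels=cell_labels,
        ffm_labels=ffm_labels,
        umi_totals=umi_totals,
        gene_counts=gene_counts,
        mito_fractions=mito_fractions,
        ffm_marker_sets=ffm_sets,
        seed=seed,
    )
    return counts, genes, barcodes, truth


def qc_boundary_fixture() -> tuple[sp.csr_matrix, list[str], list[str], list[str]]:
    """Ten hand-built cells probing each QC rule at its exact boundary.

    Four cells sit exactly on one threshold each — 400 total UMIs, 200
    expressed genes, 6000 expressed genes, 25% mitochondrial fraction —
    and six clean cells pass comfortably.  Under the strict-inequality
    convention exactly the six clean cells survive.

    Returns ``(counts cells x genes, genes, barcodes, expected_passing)``.
    """
    n_mito = 4
    genes = [f"MT-{j + 1}" for j in range(n_mito)] + [
        f"G{j + 1:05d}" for j in range(6500)
    ]

    def gidx(j: int) -> int:  # index of the j-th non-mito gene (1-based)
        return n_mito + j - 1

    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    barcodes: list[str] = []

    def add_cell(name: str, entries: dict[int, int]) -> None:
        c = len(barcodes)
        barcodes.append(name)
        for j, v in entries.items():
            rows.append(c)
            cols.append(j)
            data.append(v)

    # exactly 400 UMIs over 300 genes: fails the >400 UMI rule only
    add_cell(
        "BOUND_UMI",
        {gidx(j): (2 if j <= 100 else 1) for j in range(1, 301)},
    )
    # exactly 200 expressed genes (4 counts each): fails >200 genes only
    add_cell("BOUND_LOWGENES", {gidx(j): 4 for j in range(1, 201)})
    # exactly 6000 expressed genes (1 count each): fails <6000 genes only
    add_cell("BOUND_HIGHGENES", {gidx(j): 1 for j in range(1, 6001)})
    # exactly 25% mitochondrial: 250 of 1000 UMIs on MT-1
    entries = {0: 250}
    entries.update({gidx(j): 3 for j in range(1, 251)})
    add_cell("BOUND_MITO", entries)
    # six clean cells: 2000 UMIs, 476 genes, 5% mitochondrial
    clean = []
    for i in range(1, 7):
        name = f"CLEAN{i}"
        clean.append(name)
        entries = {0: 100}
        entries.update({gidx(j): 4 for j in range(1, 476)})
        add_cell(name, entries)

    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(barcodes), len(genes)), dtype=np.int64
    )
    return counts, genes, barcodes, clean
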