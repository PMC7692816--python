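"""Inferential layer: correlations, group comparisons, set overlaps.

Correlation significance uses the classical t approximation
``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of freedom,
applied to Spearman's rho as well (a standard, documented approximation).
Group comparisons are Mann-Whitney U tests: exact two-sided p-values by
enumeration of all group labelings for small samples (ties handled via
midranks — the permutation distribution of U remains symmetric about
``n_a * n_b / 2``), and a tie-corrected normal approximation otherwise.
Matched designs use the Wilcoxon signed-rank test when pairing is
declared.  The FFM-immune heatmap keeps genes significantly associated
with at least one module at the raw (uncorrected) alpha, matching how
such figures are typically filtered; Benjamini-Hochberg correction is
applied only inside the convenience differential-expression screen.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, SampleMetadata, ValidationError

__all__ = [
    "CorrelationRecord",
    "ComparisonRecord",
    "OverlapReport",
    "correlate",
    "ffm_immune_heatmap",
    "compare_groups",
    "disease_score_correlation",
    "overlap_sets",
    "simple_de",
]

VENN_REGIONS = ("a_only", "b_only", "c_only", "ab", "ac", "bc", "abc")


@dataclass
class CorrelationRecord:
    """One correlation test between two named vectors."""

    x_name: str
    y_name: str
    method: str
    r: float
    p_value: float
    n: int
    significant: bool
    defined: bool = True  # False when a vector had zero variance


@dataclass
class ComparisonRecord:
    """One two-group comparison (Mann-Whitney or signed-rank)."""

    feature: str
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    direction: str  # up_in_b | down_in_b | none
    test: str = "mann-whitney"


@dataclass
class OverlapReport:
    """Seven-region Venn partition of three gene lists."""

    set_names: tuple[str, str, str]
    region_counts: dict[str, int]
    region_members: dict[str, list[str]]

    def union_size(self) -> int:
        return sum(self.region_counts.values())


def _corr_and_p(
    x: np.ndarray, y: np.ndarray, method: str
) -> tuple[float, float, bool]:
    """(r, two-sided p, defined) for one pair; t approximation for p."""
    n = len(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), 1.0, False
    if method == "pearson":
        xc = x - x.mean()
        yc = y - y.mean()
        r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    elif method == "spearman":
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        xc = rx - rx.mean()
        yc = ry - ry.mean()
        r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, np.nextafter(0.0, 1.0), True
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return r, max(p, np.nextafter(0.0, 1.0)), True


def correlate(
    x: pd.Series,
    Y: pd.DataFrame | pd.Series,
    method: str = "pearson",
    alpha: float = 0.05,
) -> list[CorrelationRecord]:
    """Correlate ``x`` against every column of ``Y``.

    Pairs need at least 3 paired non-missing observations; significance of
    each record is ``p < alpha``.  Zero-variance pairs yield a record
    flagged undefined (excluded from any significance filtering).
    """
    if isinstance(Y, pd.Series):
        Y = Y.to_frame()
    records = []
    for col in Y.columns:
        pair = pd.concat([x, Y[col]], axis=1, join="inner").dropna()
        if len(pair) < 3:
            raise ValidationError(
                f"need >= 3 paired observations for {x.name!r} vs {col!r}"
            )
        xa = pair.iloc[:, 0].to_numpy(dtype=float)
        ya = pair.iloc[:, 1].to_numpy(dtype=float)
        r, p, defined = _corr_and_p(xa, ya, method)
        records.append(
            CorrelationRecord(
                x_name=str(x.name),
                y_name=str(col),
                method=method,
                r=r,
                p_value=p,
                n=len(pair),
                significant=bool(defined and p < alpha),
                defined=defined,
            )
        )
    return records


def ffm_immune_heatmap(
    activities: pd.DataFrame,
    X: ExpressionMatrix,
    immune_genes: Mapping[str, str],
    method: str = "spearman",
    alpha: float = 0.05,
    ffm_columns: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Correlation table of immune genes vs FFM activities, filtered.

    ``immune_genes`` maps gene symbol to its class (``activating`` or
    ``suppressing``).  Gene expression is ``log2(x + 1)``-transformed
    before correlating.  Rows are kept only when the gene is significantly
    associated with at least one FFM column; non-significant cells are
    masked (False in the returned mask — the "grey boxes").

    Returns ``(r_table, significance_mask, class_annotation)``; all empty
    when no gene survives the filter.
    """
    if ffm_columns is None:
        ffm_columns = [c for c in activities.columns if str(c).startswith("FFM")]
    if not ffm_columns:
        raise ValidationError("no FFM columns found in the activity table")
    present = [g for g in immune_genes if X.has_gene(g)]
    if not present:
        raise ValidationError("no immune genes present in X")
    L = X.log2_values()
    rows_r, rows_sig, kept, classes = [], [], [], []
    for g in present:
        expr = pd.Series(
            L[X.gene_indices([g])[0], :], index=X.sample_ids, name=g
        )
        recs = correlate(expr, activities[list(ffm_columns)], method, alpha)
        if any(rec.significant for rec in recs):
            kept.append(g)
            classes.append(immune_genes[g])
            rows_r.append([rec.r for rec in recs])
            rows_sig.append([rec.significant for rec in recs])
    if not kept:
        empty = pd.DataFrame(columns=list(ffm_columns))
        return empty, empty.astype(bool), pd.Series(dtype=object)
    r_table = pd.DataFrame(rows_r, index=kept, columns=list(ffm_columns))
    mask = pd.DataFrame(rows_sig, index=kept, columns=list(ffm_columns))
    return r_table, mask, pd.Series(classes, index=kept, name="class")


def _u_statistic(pooled_ranks: np.ndarray, a_idx: Sequence[int], n_a: int, n_b: int) -> float:
    ra = pooled_ranks[list(a_idx)].sum()
    return ra - n_a * (n_a + 1) / 2.0


def mannwhitney_exact_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumeration of all labelings.

    Uses midranks, so ties are handled naturally; the permutation
    distribution of U is symmetric about ``n_a * n_b / 2`` and the
    two-sided p-value is the proportion of labelings at least as far from
    that center as the observed U.  Returns ``(U_a, p)``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    mu = n_a * n_b / 2.0
    u_obs = _u_statistic(ranks, range(n_a), n_a, n_b)
    dev = abs(u_obs - mu)
    count = 0
    total = 0
    for comb in itertools.combinations(range(n_a + n_b), n_a):
        u = _u_statistic(ranks, comb, n_a, n_b)
        if abs(u - mu) >= dev - 1e-9:
            count += 1
        total += 1
    return float(u_obs), count / total


def compare_groups(
    values: pd.Series | np.ndarray,
    metadata: SampleMetadata,
    group_a: str,
    group_b: str,
    feature: str = "feature",
    paired: bool = False,
    exact_max_n: int = 8,
) -> ComparisonRecord:
    """Two-group comparison of a per-sample feature.

    Unpaired comparisons use the Mann-Whitney U test: exact enumeration
    when both groups have at most ``exact_max_n`` samples, otherwise the
    tie-corrected normal approximation.  With ``paired=True`` (matched
    designs such as primary/metastasis pairs, matched by order within each
    group) the Wilcoxon signed-rank test is used.  Direction compares
    medians of group b against group a.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) != len(metadata.sample_ids):
        raise ValidationError("values length does not match metadata")
    for g in (group_a, group_b):
        if g not in metadata.group:
            raise ValidationError(f"group {g!r} absent from metadata")
    a = vals[metadata.group_mask(group_a)]
    b = vals[metadata.group_mask(group_b)]
    if paired:
        if len(a) != len(b) or len(a) < 2:
            raise ValidationError("paired test needs equal group sizes >= 2")
        diff = b - a
        if np.all(diff == 0):
            stat, p = 0.0, 1.0
        else:
            res = sps.wilcoxon(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
        test = "wilcoxon-signed-rank"
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValidationError("need >= 2 samples per group")
        if len(a) <= exact_max_n and len(b) <= exact_max_n:
            stat, p = mannwhitney_exact_p(a, b)
            test = "mann-whitney-exact"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
            test = "mann-whitney-asymptotic"
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_b > med_a:
        direction = "up_in_b"
    elif med_b < med_a:
        direction = "down_in_b"
    else:
        direction = "none"
    return ComparisonRecord(
        feature=feature,
        group_a=group_a,
        group_b=group_b,
        statistic=stat,
        p_value=p,
        direction=direction,
        test=test,
    )


def disease_score_correlation(
    activities: pd.DataFrame,
    metadata: SampleMetadata,
    method: str = "pearson",
    alpha: float = 0.05,
    ffm_columns: Sequence[str] | None = None,
) -> list[CorrelationRecord]:
    """Correlate each FFM activity with the disease score (one record each)."""
    if metadata.disease_score is None:
        raise ValidationError("metadata has no disease_score")
    meta = metadata.aligned_to(list(activities.index))
    score = pd.Series(meta.disease_score, index=activities.index, name="disease_score")
    if ffm_columns is None:
        ffm_columns = [c for c in activities.columns if str(c).startswith("FFM")]
    records = []
    for col in ffm_columns:
        records.extend(correlate(activities[col], score, method, alpha))
    return records


def overlap_sets(
    list_a: Sequence[str],
    list_b: Sequence[str],
    list_c: Sequence[str],
    set_names: tuple[str, str, str] = ("A", "B", "C"),
) -> OverlapReport:
    """Exact 7-region Venn partition of three gene lists."""
    for name, lst in zip(set_names, (list_a, list_b, list_c)):
        if len(set(lst)) != len(list(lst)):
            raise ValidationError(f"list {name!r} contains duplicates")
    A, B, C = set(list_a), set(list_b), set(list_c)
    regions = {
        "a_only": A - B - C,
        "b_only": B - A - C,
        "c_only": C - A - B,
        "ab": (A & B) - C,
        "ac": (A & C) - B,
        "bc": (B & C) - A,
        "abc": A & B & C,
    }
    return OverlapReport(
        set_names=tuple(set_names),
        region_counts={k: len(v) for k, v in regions.items()},
        region_members={k: sorted(v) for k, v in regions.items()},
    )


def simple_de(
    X: ExpressionMatrix,
    metadata: SampleMetadata,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Nonparametric differential-expression screen for synthetic pipelines.

    Per-gene Mann-Whitney on ``log2(x + 1)`` values with Benjamini-Hochberg
    adjustment; returns the genes significant at ``alpha`` with their
    direction (``up_in_b`` / ``down_in_b``).  This is a testing
    convenience, not a replacement for a count-model DE method on real
    sequencing data.
    """
    meta = metadata.aligned_to(list(X.sample_ids))
    mask_a = meta.group_mask(group_a)
    mask_b = meta.group_mask(group_b)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValidationError("need >= 2 samples per group")
    L = X.log2_values()
    A = L[:, mask_a]
    B = L[:, mask_b]
    pvals = np.ones(X.n_genes)
    stats_ = np.zeros(X.n_genes)
    for i in range(X.n_genes):
        if np.ptp(np.concatenate([A[i], B[i]])) == 0:
            continue
        res = sps.mannwhitneyu(A[i], B[i], alternative="two-sided", method="asymptotic")
        stats_[i], pvals[i] = res.statistic, res.pvalue
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    med_diff = np.median(B, axis=1) - np.median(A, axis=1)
    frame = pd.DataFrame(
        {
            "gene": X.gene_ids,
            "statistic": stats_,
            "p_value": pvals,
            "q_value": qvals,
            "direction": np.where(med_diff > 0, "up_in_b", "down_in_b"),
            "significant": reject,
        }
    )
    return frame[frame["significant"]].reset_index(drop=True)
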