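# Methods

## Model

Bulk tissue expression is modelled as a non-negative mixture

    X ≈ S · P,      X: genes × samples, S: genes × types, P: types × samples

where the columns of S are cell-type signatures and the columns of P are
relative cell-type abundances in each sample.  Prior marker knowledge
enters through a labeling matrix C (genes × types, entries in [0, 1], 1
meaning the gene is a known marker of the type).  The fit minimizes

    ‖X − S·P‖²_F + λ · Σ_{g,k} S[g,k] · (1 − C[g,k]),      S, P ≥ 0

an L1 penalty on signature mass outside the labeled markers.  As λ → ∞
the signatures concentrate on the marker genes and P degenerates to
(weighted) marker averages; at λ = 0 the problem is plain NMF.

Optimization uses multiplicative updates (Frobenius-loss scheme with the
linear penalty absorbed into the S denominator), which preserve
non-negativity and never increase the objective; the implementation
records the objective every iteration and raises if it ever increases
beyond numerical tolerance.  Scale ambiguity is fixed by convention:
after convergence each column of S is L1-normalized and P is rescaled
compensatingly, leaving S·P unchanged to machine precision.  Relative —
not absolute — proportions are identified; a per-sample sum-to-one
renormalization is available for display.

**Tunable parameters.** λ defaults to mean(X) (the penalty then acts on
the scale of a typical expression value); `lambda_sensitivity` refits
across a sweep.  Convergence: relative objective change < 1e-6 or 2000
iterations.  Initialization: `marker_mean` (deterministic; signature
columns from the mean expression of each type's labeled genes with a 1e-6
floor, P by non-negative least squares) or `random` (seeded).

## Rank estimation and marker refinement

The number of detectable components is estimated by bi-cross-validation
in the Owen–Perry block scheme: rows and columns are randomly partitioned
(default 2 folds per axis, 20 repetitions), and each held-out block X22
is predicted from the training blocks as X21 · pinv_r(X11) · X12, where
pinv_r is the pseudo-inverse of the rank-r truncated SVD of X11.  The
selected rank minimizes mean held-out squared error; ranks whose error is
within numerical tolerance of the minimum tie-break to the smallest, so
noiseless data of true rank r selects exactly r.

Dataset-specific marker modules are refined by nonparametric hub/module
detection within each type's prior list: the hub gene maximizes the
summed Spearman correlation to the other labeled genes (lexicographic
tie-break), and the module keeps genes whose correlation with the hub
reaches `corr_threshold` (default 0.5).  Types whose surviving module is
smaller than `min_module_size` (default 3) are reported undetectable in
that dataset.  Refinement filters the prior list and never invents
markers; zero-variance genes are excluded and cannot become hubs.  The
exact statistic of the original rank test and the original module
detector are not published in detail; the BCV scheme and
Spearman-hub rule implemented here are standard formulations and are the
package's own choices.

## Per-sample scores

Fibroblast functional-module activity (FFM1 non-collagen, FFM2 collagen
1/3/5, FFM3 collagen 4, FFM4 collagen 6) is the arithmetic mean of
log2(x+1)-transformed expression of the module's markers in each sample.
The log transform prevents a single highly expressed collagen from
dominating; internal computation otherwise stays on the linear scale.

Relative T-cell cytotoxicity is log2 of the ratio of mean cytotoxic
effector expression (defaults PRF1, GZMA) to mean pan-T-cell marker
expression (defaults CD2, CD3D; "CD3" is a complex, so a concrete subunit
is named, and the gene lists are configurable).  The pseudocount (default
1) is added to both numerator and denominator only when one of the means
is zero, and the score is computed in a sign-stable form (magnitude from
the larger/smaller ratio).  Consequences: the score is exactly 0 at equal
means, exactly negated when the two gene groups are swapped, and exactly
invariant to a common scale factor whenever both means are positive and
the scaled products are exactly representable.

Cell-type-specific functional activity (second-round NMF): the marker
genes of a (type, function) pair are assumed type-specific, so their bulk
expression tracks proportion × intensity.  A rank-1 NMF (alternating
non-negative least squares) of those genes yields a per-sample loading;
dividing by the type's estimated proportion reports intensity per unit of
cell type.  An explicit residualization against the other types'
proportion rows is deliberately omitted: proportions are compositional
(they share a dominant common component), so an unpenalized non-negative
regression absorbs much of the target signal and the clipped residual no
longer carries the proportion-times-intensity structure.

## Inference

Correlation significance uses t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of
freedom, applied to Spearman's rho as well — a standard approximation,
documented as such.  Both Pearson and Spearman are exposed because the
source analyses are described inconsistently across text and figure
legends; Spearman is the heatmap default.  The immune-gene heatmap keeps
genes significant for at least one FFM at raw alpha = 0.05 with no
multiplicity correction, mirroring how such figure filters are stated;
Benjamini–Hochberg correction is applied only in the convenience
differential-expression screen (`simple_de`), which is a nonparametric
stand-in used to feed synthetic overlap analyses, not a count-model DE
method.

Group comparisons are Mann–Whitney U tests.  For groups of at most 8 the
two-sided p-value is exact: all C(n, n_a) labelings are enumerated with
midranks, whose permutation distribution of U is symmetric about
n_a·n_b/2, so ties are handled without approximation.  Larger groups use
the tie-corrected normal approximation.  Declared matched designs use the
Wilcoxon signed-rank test instead; unpaired is the default.

Three-list overlaps are exact 7-region Venn partitions; region counts
satisfy inclusion–exclusion identically by construction.

## Single-cell validation

Barcodes are filtered on strict inequalities exactly as the thresholds
are printed: UMIs > 400, 200 < genes < 6000, mitochondrial fraction
(UMIs on "MT-"-prefixed genes over total UMIs) < 25%.  Boundary cells
fail.  Surviving cells are normalized by library-size scaling to 10,000
followed by ln(1+x) (the common single-cell toolkit default, reproduced
as a formula and cross-checked against scanpy in the tests).  Per-cell
FFM scores are mean normalized marker expression; Welch's two-sided
t-test compares fibroblasts against all other cells per module.
Fibroblasts are assigned to the argmax module, or to "Others" when the
best score does not exceed `min_score` (default 0 — no marker
expression) or the top is tied.  Clustering, PCA, cell-cycle/UMI
regression and cell-type annotation are not reimplemented; cell-type
labels are consumed as input.

## Synthetic data

The generators encode the study conditions used by the tests: Dirichlet
proportions (columns sum to one, giving an unambiguous recovery target),
signatures with planted marker genes at a configurable fold (default 10)
over a gene-specific baseline, and multiplicative log-normal noise
(default sd 0.2 in recovery studies) so values stay non-negative and
heteroskedastic.  Coupled immune genes are exponential transforms of the
target type's standardized proportion: linear on the log scale, so the
coupling sign sets the rank-correlation sign.  Single-cell counts are
per-gene Poisson with rates scaled to log-normal library sizes (mean
2000 UMIs, log-sd 0.5); fibroblasts express their subgroup's markers at
fold 5, "Others" fibroblasts express none of the four panels, and
mitochondrial genes receive an expected `mito_mean` fraction of counts.

What this does not emulate: real expression distributions, batch
effects, dropout curves, doublets, or mouse/human symbol differences.
Passing tests therefore demonstrate that the estimators recover the
truths of this generative family under the stated noise, not performance
on any particular public dataset.

## Numerical choices and degenerate inputs

Multiplicative updates carry a 1e-12 denominator floor; all-zero gene
rows are dropped with a warning; an objective increase raises with the
trace attached.  BCV ties resolve to the smallest rank within a
tolerance of 1e-10 of the mean-square scale of X; degenerate partitions
are retried up to 10 times.  Zero-variance vectors in correlations yield
records flagged undefined and excluded from significance filtering.
Gene identifiers are matched case-insensitively after trimming;
mouse/human mapping is the caller's responsibility.  Problem sizes in
the test suite (200 genes × 60 samples × 5 types, 20 seeds, 500
fibroblasts, 1000 null replicates) are the package's chosen study
conditions throughout.

## Known limitations

Proportions are relative; no absolute-fraction calibration, confidence
intervals, or batch correction.  The penalty weight λ is a modelling
choice with a sensitivity utility, not an estimated quantity.  The
t-approximation for Spearman significance is slightly anticonservative
at very small n.  The heatmap filter intentionally performs no multiple
testing correction.
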