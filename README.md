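# tmedeconv

Marker-guided deconvolution of the tumor microenvironment from bulk
RNA-seq, with fibroblast functional-module scoring, tumor-immune
correlation analysis, and single-cell validation.

Solid tumors — ovarian cancer prominently among them — are mixtures of
cancer cells, fibroblasts, immune cells, endothelial cells and
adipocytes, and the balance of those populations shapes immune
infiltration and therapy response.  Cancer-associated fibroblasts are
themselves heterogeneous: four functional modules (FFM1 non-collagen,
FFM2 collagen 1/3/5, FFM3 collagen 4, FFM4 collagen 6) behave
differently, and the collagen 1/3/5 module in particular tracks
immune-suppressive gene expression.  `tmedeconv` is a tested,
end-to-end implementation of the analysis that quantifies these
populations from bulk expression and relates them to immune features,
exercised against synthetic data with known ground truth.

## The model

Bulk expression X (genes × samples) is factored as X ≈ S·P with
non-negative signatures S and relative proportions P, guided by a prior
marker labeling matrix C through the penalized objective

    min_{S,P ≥ 0}  ‖X − S·P‖²_F + λ · Σ_{g,k} S[g,k] (1 − C[g,k])

solved by multiplicative updates (monotone objective, recorded every
iteration).  Around the factorization the package provides:

- **Rank selection** by Owen–Perry bi-cross-validation (held-out block
  predicted from the complementary blocks at each candidate rank).
- **Marker refinement** by Spearman hub/module detection within each
  cell type's prior marker list.
- **Per-sample scores**: FFM activities (mean log2(x+1) marker
  expression) and relative T-cell cytotoxicity (log2 ratio of
  PRF1/GZMA to CD2/CD3D expression).
- **Inference**: Pearson/Spearman correlation records with t-based
  significance, exact (enumerated) Mann–Whitney tests for small groups,
  disease-score correlations, FFM–immune-gene heatmap tables with
  significance masking, and exact three-way Venn partitions of gene
  lists.
- **Single-cell validation**: QC filtering at strict thresholds
  (UMIs > 400, 200 < genes < 6000, mitochondrial fraction < 25%),
  library-size + log1p normalization, per-cell FFM scoring, fibroblast
  enrichment t-tests, and FFM subgroup assignment.
- **Synthetic data generators** for every stage, with hidden ground
  truth (Dirichlet mixtures, coupled immune genes, Poisson UMI counts).

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```python
import numpy as np
from tmedeconv import (generate_signatures, generate_mixture,
                       constrained_nmf, build_labeling_matrix,
                       estimate_rank_bcv)

types = ["fibroblast", "Tcell", "Bcell", "myeloid", "endothelial"]
S, sets = generate_signatures(200, types, markers_per_type=5,
                              marker_fold=10.0, seed=0)
X, truth = generate_mixture(S, 60, [1.0] * 5, noise_sd=0.1, seed=0,
                            marker_sets=sets)

rank, errors = estimate_rank_bcv(X, max_rank=8, seed=0)
print("selected rank:", rank)

labeling = build_labeling_matrix(sets, X.gene_ids)
result = constrained_nmf(X, labeling, seed=0)
for k, name in enumerate(result.type_names):
    r = np.corrcoef(result.P[k], truth.P_true[k])[0, 1]
    print(f"  {name:12s} recovery r = {r:.3f}")
```

prints

```
selected rank: 5
  fibroblast   recovery r = 0.995
  Tcell        recovery r = 0.996
  Bcell        recovery r = 0.995
  myeloid      recovery r = 0.995
  endothelial  recovery r = 0.995
```

Bi-cross-validation finds the five mixed populations from the data
alone, and the penalized factorization recovers each hidden proportion
profile almost perfectly (Pearson r against the generator's truth) at
10% multiplicative noise.

The same stages are available from the shell:

```sh
tmedeconv simulate   --out-dir run --seed 1
tmedeconv markers    --out-dir run --expression run/expression.tsv --marker-file run/markers.tsv
tmedeconv deconvolve --out-dir run --expression run/expression.tsv --marker-file run/markers.tsv
tmedeconv score      --out-dir run --expression run/expression.tsv --ffm-file run/markers.tsv
tmedeconv report     --out-dir run
```

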