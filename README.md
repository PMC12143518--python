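# wmc — M-band wavelet multi-view clustering of single cells

Standard single-cell RNA-seq pipelines cluster one matrix and produce one
partition, which can blur fine-grained cell states into their parent cell
types. `wmc` decomposes a QC'd, log-normalized gene × cell expression matrix
`S ∈ ℝ^{n×p}` with an orthogonal M-band discrete wavelet transform
`W` (n = Mk) into

    S = Wᵀ W S = A + D₁ + … + D_{M−1}

an *approximation* component `A` (the projection of each cell's profile onto
the scaling subspace 𝒱 — a smoothed, weighted-average-like view) and M−1
*detail* components `D_j` (projections onto the mutually orthogonal wavelet
subspaces 𝒲_j, which carry local contrasts between neighboring genes).
Because `W` is orthogonal, the decomposition preserves energy
(‖s‖² = ‖a‖² + Σ‖d_j‖²) and reconstructs perfectly. Each component — plus
the untransformed original — is then clustered independently with the
standard graph pipeline (PCA → shared-nearest-neighbor KNN graph → Louvain),
giving a *multi-view* clustering: the approximation view tracks the
conventional result while detail views can resolve sub-structure that is
diluted in the full matrix.

The multi-view result is assessed two ways:

* **Marker-set intersection analysis.** With marker sets G₀ (original view),
  G₁ (approximation), G₂..G_M (details), every non-empty subset Λ of views
  gets its exclusive cell N_Λ = (∩_{i∈Λ} G_i) \ (∪_{j∉Λ} G_j) — an
  UpSet-style partition of the union. Orthogonality of the components
  predicts small cross-component cells (|Λ| ≥ 2 without the original view);
  their total is reported as a leakage diagnostic.
* **Concordance.** Pairwise adjusted Rand index (ARI, pair-counting
  corrected for chance, in [−1, 1]) and normalized mutual information
  (NMI, I(A;B)/√(H(A)H(B)), in [0, 1]) between the views' partitions.

The package is for computational biologists who want a second, multi-scale
look at a dataset without changing their toolchain: the core objects are
scikit-learn estimators (`MBandDWT`, `WaveletMultiViewClustering`) that
compose with sklearn pipelines, and a thin CLI drives the end-to-end flow.

## Worked example

Simulate a dataset with 4 planted cell types (marker fold change e²) each
split into 2 states whose alternating marker-pair shifts cancel in the
approximation and concentrate in the 2-band detail component, then run the
pipeline and score recovery:

```python
from wmc.synthetic import strong_signal_config, simulate_counts, evaluate_recovery
from wmc.multiview import run_multiview, PipelineConfig, EmbeddingConfig

X, truth = simulate_counts(strong_signal_config(seed=0))   # 1200 genes x 800 cells
cfg = PipelineConfig(M=2, family="haar", compute_umap=False,
                     embedding=EmbeddingConfig(seed=0))
result = run_multiview(X, cfg)
print(evaluate_recovery(truth, result).to_string(index=False))
```

```
    view  n_clusters  ari_major  nmi_major  ari_sub  nmi_sub
original           5   0.912696   0.942813 0.667320 0.855330
  approx           4   1.000000   1.000000 0.597886 0.816497
detail-1           8   0.492972   0.638056 0.829952 0.817916
```

Reading the table: the approximation view recovers the 4 planted cell types
exactly (ARI vs type labels = 1.0; the original view splits one type and
scores 0.91), but neither resolves the 8 states — against the planted state
labels they score only 0.60–0.67. The detail view, where the type signal
cancels and the state contrast survives, finds 8 clusters and resolves the
states markedly better (ARI 0.83) — the multi-view gain the method is
designed for. Its low `ari_major` is expected: a partition of types into
states disagrees with the 4-way type labels by construction.

The same flow from the shell:

```sh
wmc simulate --outdir sim --seed 0
wmc run --input sim --format 10x-mtx --bands 2 --family haar \
    --seed 0 --no-umap --assess --outdir out
# out/: labels.csv, intersection.csv, concordance.csv, manifest.json, wmc.log
```

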