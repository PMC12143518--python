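"""Multi-view clustering pipeline.

The normalized gene x cell matrix is decomposed by an M-band DWT into an
approximation view and M-1 detail views; each view (plus the
untransformed original) is then clustered independently with the
standard single-cell graph pipeline: PCA -> shared-nearest-neighbor KNN
graph -> Louvain community detection.  UMAP embeddings are computed for
visualization only and never feed the clustering.

Clustering runs on the k x p coefficient matrices rather than the n x p
gene-level reconstructions: the reconstruction is the coefficient block
mapped through orthonormal rows, so pairwise cell distances — and hence
the KNN graph — are identical in either representation.  Marker
detection (see :mod:`wmc.assessment`) uses the reconstructions, where
gene identity is preserved.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field, asdict

import igraph as ig
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.metrics import pairwise_distances

from .dwt import build_dwt_matrix, forward_dwt, pad_genes, reconstruct_component
from .filters import build_filter_bank
from .preprocessing import (
    NormalizedMatrix,
    QCThresholds,
    RawCountMatrix,
    compute_qc_metrics,
    filter_cells,
    filter_genes,
    log_normalize,
)

__all__ = [
    "ClusterAssignment",
    "EmbeddingConfig",
    "MultiViewResult",
    "PipelineConfig",
    "StageError",
    "View",
    "ViewSet",
    "WaveletMultiViewClustering",
    "build_knn_graph",
    "cluster_graph",
    "decompose_views",
    "embed_pca",
    "embed_umap",
    "run_multiview",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class EmbeddingConfig:
    """Per-view embedding and clustering parameters."""

    n_pcs: int = 30
    k_neighbors: int = 20
    resolution: float = 1.0
    umap_dims: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_pcs, self.k_neighbors) <= 0 or self.resolution <= 0:
            raise ValueError("n_pcs, k_neighbors and resolution must be positive")
        if self.umap_dims not in (2, 3):
            raise ValueError("umap_dims must be 2 or 3")


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-cell integer labels for one view, with provenance."""

    labels: np.ndarray
    view_label: str
    parameters: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)


@dataclass(frozen=True)
class View:
    """One view: label, k x p coefficients (None for the original) and
    the gene-level reconstruction (padded length x p)."""

    label: str
    coefficients: np.ndarray | None
    reconstruction: np.ndarray


@dataclass(frozen=True)
class ViewSet:
    """The original view plus the M wavelet-component views."""

    views: tuple
    M: int
    family: str
    padding: int
    gene_ids: np.ndarray  # unpadded gene ids (reconstruction rows [0, n_genes))

    @property
    def labels(self) -> list:
        return [v.label for v in self.views]

    def view(self, label: str) -> View:
        for v in self.views:
            if v.label == label:
                return v
        raise KeyError(f"no view {label!r}; have {self.labels}")

    @property
    def pad_mask(self) -> np.ndarray:
        """Boolean mask over padded rows (True = zero pad row)."""
        n_pad = self.views[0].reconstruction.shape[0]
        mask = np.zeros(n_pad, dtype=bool)
        mask[n_pad - self.padding:] = self.padding > 0
        return mask


def decompose_views(
    S_norm: NormalizedMatrix | np.ndarray,
    M: int = 2,
    family: str | None = None,
    gene_ids=None,
) -> ViewSet:
    """Decompose a normalized matrix into original + M component views."""
    if isinstance(S_norm, NormalizedMatrix):
        vals, gene_ids = S_norm.values, S_norm.gene_ids
    else:
        vals = np.asarray(S_norm, dtype=float)
        if gene_ids is None:
            gene_ids = np.array([f"g{i}" for i in range(vals.shape[0])], dtype=object)
    if not np.all(np.isfinite(vals)):
        raise ValueError("normalized matrix contains non-finite values")
    padded, padding = pad_genes(vals, M)
    fb = build_filter_bank(M, family)
    Wm = build_dwt_matrix(fb, padded.shape[0])
    C = forward_dwt(Wm, padded, padding=padding)
    views = [View("original", None, padded)]
    for label in Wm.block_labels:
        views.append(View(label, C.block(label), reconstruct_component(Wm, C, label)))
    return ViewSet(tuple(views), M=M, family=fb.family,
                   padding=padding, gene_ids=np.asarray(gene_ids, dtype=object))


def embed_pca(X, n_pcs: int = 30, seed: int = 0) -> np.ndarray:
    """PCA scores of a feature x cell matrix, cells in rows.

    Features are centered; components are sign-fixed so the
    largest-magnitude loading of each component is positive, making the
    scores reproducible across SVD backends.
    """
    X = np.asarray(X, dtype=float)
    Y = X.T  # cells x features
    if n_pcs > min(Y.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix rank bound {min(Y.shape)}")
    if np.allclose(Y.var(axis=0), 0):
        raise ValueError("matrix is constant; PCA undefined")
    pca = PCA(n_components=n_pcs, random_state=seed)
    scores = pca.fit_transform(Y)
    flip = np.sign(
        pca.components_[np.arange(n_pcs), np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    return scores * flip


def build_knn_graph(scores: np.ndarray, k_neighbors: int = 20) -> ig.Graph:
    """Shared-nearest-neighbor graph over cells.

    Each cell is linked to its ``k_neighbors`` Euclidean nearest
    neighbors (distance ties broken by ascending cell index); the union
    of directed links is kept, weighted by the Jaccard overlap of the
    two cells' neighbor sets (self included), giving symmetric weights
    in (0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    p = scores.shape[0]
    if k_neighbors >= p:
        raise ValueError(f"k_neighbors={k_neighbors} must be < number of cells {p}")
    D = pairwise_distances(scores)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")[:, :k_neighbors]
    N = np.zeros((p, p), dtype=bool)
    N[np.repeat(np.arange(p), k_neighbors), order.ravel()] = True
    np.fill_diagonal(N, True)  # neighbor sets include self
    directed = N.copy()
    np.fill_diagonal(directed, False)
    adj = directed | directed.T
    Ni = N.astype(np.int32)
    inter = Ni @ Ni.T
    sizes = Ni.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    iu, ju = np.nonzero(np.triu(adj, 1))
    weights = inter[iu, ju] / union[iu, ju]
    g = ig.Graph(n=p, edges=list(zip(iu.tolist(), ju.tolist())))
    g.es["weight"] = weights.tolist()
    return g


def cluster_graph(
    graph: ig.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    view_label: str = "",
) -> ClusterAssignment:
    """Louvain community detection on a weighted cell graph.

    Deterministic given ``seed``; labels are relabeled to contiguous
    integers ordered by decreasing cluster size (ties by first
    appearance).
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    rng = _random.Random(seed)
    ig.set_random_number_generator(rng)
    try:
        part = graph.community_multilevel(
            weights="weight" if "weight" in graph.es.attributes() else None,
            resolution=resolution,
        )
    finally:
        ig.set_random_number_generator(_random)
    raw = np.asarray(part.membership)
    ids, counts = np.unique(raw, return_counts=True)
    first_seen = np.array([np.argmax(raw == i) for i in ids])
    order = ids[np.lexsort((first_seen, -counts))]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[x] for x in raw], dtype=int)
    return ClusterAssignment(
        labels=labels,
        view_label=view_label,
        parameters={"resolution": resolution, "seed": seed},
    )


def embed_umap(scores: np.ndarray, config: EmbeddingConfig) -> np.ndarray:
    """UMAP coordinates for visualization (never used for clustering)."""
    import umap  # deferred: numba compilation is expensive

    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] <= config.k_neighbors:
        raise ValueError(
            f"need more cells than k_neighbors={config.k_neighbors} for UMAP"
        )
    reducer = umap.UMAP(
        n_components=config.umap_dims,
        n_neighbors=config.k_neighbors,
        random_state=config.seed,
    )
    return np.asarray(reducer.fit_transform(scores))


class WaveletMultiViewClustering(ClusterMixin, BaseEstimator):
    """Multi-view wavelet clustering as a scikit-learn estimator.

    ``fit(X)`` takes a normalized ``(n_cells, n_genes)`` array, builds
    the component views and clusters each one.  ``labels_`` carries the
    original-view labels (the drop-in single-view result); the full
    multi-view output lives in ``labels_per_view_``.

    Parameters
    ----------
    M : int, default 2
        Wavelet band count (views = M + 1 including the original).
    family : str or None
        Filter family (None = per-M default, Daubechies for 2-band).
    n_pcs, k_neighbors, resolution : embedding/clustering parameters.
    random_state : int
        Seed shared by every stochastic stage in every view.

    Attributes
    ----------
    viewset_ : ViewSet
    assignments_ : dict of view label -> ClusterAssignment
    labels_per_view_ : dict of view label -> ndarray
    labels_ : ndarray  (original view)
    n_clusters_per_view_ : dict
    """

    def __init__(self, M: int = 2, family: str | None = None, n_pcs: int = 30,
                 k_neighbors: int = 20, resolution: float = 1.0,
                 random_state: int = 0):
        self.M = M
        self.family = family
        self.n_pcs = n_pcs
        self.k_neighbors = k_neighbors
        self.resolution = resolution
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.viewset_ = decompose_views(X.T, M=self.M, family=self.family)
        self.assignments_ = {}
        self.scores_per_view_ = {}
        for v in self.viewset_.views:
            mat = v.reconstruction if v.coefficients is None else v.coefficients
            n_pcs = min(self.n_pcs, *mat.shape)
            scores = embed_pca(mat, n_pcs=n_pcs, seed=self.random_state)
            graph = build_knn_graph(scores, self.k_neighbors)
            asg = cluster_graph(graph, self.resolution, self.random_state, v.label)
            self.scores_per_view_[v.label] = scores
            self.assignments_[v.label] = asg
        self.labels_per_view_ = {k: a.labels for k, a in self.assignments_.items()}
        self.labels_ = self.labels_per_view_["original"]
        self.n_clusters_per_view_ = {
            k: a.n_clusters for k, a in self.assignments_.items()
        }
        return self


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration: QC, normalization, transform, embedding."""

    qc: QCThresholds = QCThresholds()
    scale_factor: float = 1e4
    norm_method: str = "library-size"
    M: int = 2
    family: str | None = None
    embedding: EmbeddingConfig = EmbeddingConfig()
    compute_umap: bool = True
    gene_order: str = "input"  # input | alphabetical | mean-descending

    def provenance(self) -> dict:
        d = asdict(self)
        d["family"] = self.family
        return d


@dataclass(frozen=True)
class MultiViewResult:
    """Everything a run produces: labels, embeddings, views, provenance."""

    assignments: dict
    umap_coords: dict
    viewset: ViewSet
    barcodes: np.ndarray
    cell_qc_log: object
    provenance: dict

    @property
    def view_labels(self) -> list:
        return list(self.assignments.keys())


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001 - annotate with stage name
                raise StageError(name, e) from e
        return wrapped
    return deco


def _reorder_genes(X: RawCountMatrix, how: str) -> RawCountMatrix:
    if how == "input":
        return X
    if how == "alphabetical":
        idx = np.argsort(X.gene_ids.astype(str), kind="stable")
    elif how == "mean-descending":
        means = np.asarray(X.counts.mean(axis=1)).ravel()
        idx = np.argsort(-means, kind="stable")
    else:
        raise ValueError(f"unknown gene_order {how!r}")
    return RawCountMatrix(X.counts[idx], X.gene_ids[idx], X.barcodes,
                          mito_mask=X.mito_mask[idx])


def run_multiview(X_raw: RawCountMatrix, config: PipelineConfig = PipelineConfig()
                  ) -> MultiViewResult:
    """Run the full pipeline: QC -> normalize -> decompose -> cluster per view.

    Every stochastic stage shares ``config.embedding.seed``; rerunning
    with the same inputs and configuration reproduces identical labels.
    Stage failures abort with the stage name attached.
    """
    emb = config.embedding
    metrics = _stage("qc-metrics")(compute_qc_metrics)(X_raw)
    X_cells, cell_log = _stage("filter-cells")(filter_cells)(X_raw, metrics, config.qc)
    X_qc = _stage("filter-genes")(filter_genes)(X_cells, config.qc)
    X_qc = _stage("gene-order")(_reorder_genes)(X_qc, config.gene_order)
    S = _stage("normalize")(log_normalize)(X_qc, config.scale_factor, config.norm_method)

    def _fit():
        est = WaveletMultiViewClustering(
            M=config.M, family=config.family, n_pcs=emb.n_pcs,
            k_neighbors=emb.k_neighbors, resolution=emb.resolution,
            random_state=emb.seed,
        )
        est.fit(S.values.T)
        return est

    est = _stage("multiview-clustering")(_fit)()
    # re-attach gene ids lost by the estimator's array-only interface
    viewset = ViewSet(est.viewset_.views, est.viewset_.M, est.viewset_.family,
                      est.viewset_.padding, S.gene_ids)
    umap_coords = {}
    if config.compute_umap:
        for label, scores in est.scores_per_view_.items():
            umap_coords[label] = _stage("umap")(embed_umap)(scores, emb)
    provenance = {
        "config": config.provenance(),
        "n_cells_raw": int(X_raw.n_cells),
        "n_genes_raw": int(X_raw.n_genes),
        "n_cells_qc": int(X_qc.n_cells),
        "n_genes_qc": int(X_qc.n_genes),
        "M": config.M,
        "family": viewset.family,
        "padding": int(viewset.padding),
        "seed": emb.seed,
    }
    return MultiViewResult(
        assignments=est.assignments_,
        umap_coords=umap_coords,
        viewset=viewset,
        barcodes=S.barcodes,
        cell_qc_log=cell_log,
        provenance=provenance,
    )
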