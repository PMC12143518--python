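"""Multi-view assessment: markers, set intersections, ARI/NMI concordance.

Marker genes are detected per view with a two-sided Wilcoxon rank-sum
test of each cluster against all remaining cells, Benjamini-Hochberg
adjusted across genes within each cluster comparison; a gene is a marker
when the adjusted p-value is at most ``alpha`` and the absolute mean
difference is at least ``min_abs_effect``.

Given the marker sets G_0 (original view), G_1 (approximation) and
G_2..G_M (detail views), the intersection analysis computes, for every
non-empty subset L of {0..M}, the exclusive cell

    N_L = (intersection of G_i, i in L)  minus  (union of G_j, j not in L)

i.e. the genes significant in exactly the views of L.  The N_L over all
non-empty L partition the union of the sets (UpSet-style decomposition).
Because distinct wavelet components live in orthogonal subspaces, cells
with |L| >= 2 that exclude the original view are expected to be small;
their total is reported as the cross-component leakage diagnostic.

Partition agreement uses the adjusted Rand index computed exactly from
the contingency table n_ij,

    ARI = [sum_ij C(n_ij,2) - E] / [(sum_i C(a_i,2) + sum_j C(b_j,2))/2 - E],
    E   = sum_i C(a_i,2) * sum_j C(b_j,2) / C(N,2),

and the normalized mutual information I(A;B) / sqrt(H(A) H(B)).
Degenerate cases (zero denominator / zero entropy) return 1 for
identical partitions and raise :class:`DegeneratePartitionError`
otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConcordanceReport",
    "DegeneratePartitionError",
    "GeneSetCollection",
    "IntersectionReport",
    "MarkerResult",
    "ari",
    "find_markers",
    "intersection_analysis",
    "nmi",
    "pairwise_concordance",
]


class DegeneratePartitionError(ValueError):
    """ARI/NMI undefined for this pair of partitions."""


def _labels(x) -> np.ndarray:
    labels = getattr(x, "labels", x)
    return np.asarray(labels)


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ai, aidx = np.unique(a, return_inverse=True)
    bi, bidx = np.unique(b, return_inverse=True)
    table = np.zeros((len(ai), len(bi)), dtype=np.int64)
    np.add.at(table, (aidx, bidx), 1)
    return table


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    table = _contingency(a, b)
    return bool(np.all((table > 0).sum(axis=0) == 1) and np.all((table > 0).sum(axis=1) == 1))


def ari(A, B) -> float:
    """Adjusted Rand index between two labelings of the same cells.

    Accepts label arrays or ClusterAssignment objects.  Identical
    partitions give 1 even in degenerate cases (all-singleton or
    single-cluster); other zero-denominator cases raise
    :class:`DegeneratePartitionError`.
    """
    a, b = _labels(A), _labels(B)
    if a.shape != b.shape:
        raise ValueError(f"label lengths differ: {a.shape} vs {b.shape}")
    table = _contingency(a, b)
    n = a.size

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0:
        if _same_partition(a, b):
            return 1.0
        raise DegeneratePartitionError(
            "ARI denominator is zero and the partitions differ"
        )
    return float((sum_ij - expected) / denom)


def nmi(A, B) -> float:
    """Normalized mutual information, geometric-mean normalization.

    ``I(A;B) / sqrt(H(A) * H(B))`` in [0, 1].  A zero-entropy partition
    (single cluster) is only defined against an identical partition
    (returns 1); otherwise raises :class:`DegeneratePartitionError`.
    """
    a, b = _labels(A), _labels(B)
    if a.shape != b.shape:
        raise ValueError(f"label lengths differ: {a.shape} vs {b.shape}")
    table = _contingency(a, b).astype(float)
    n = a.size
    pa = table.sum(axis=1) / n
    pb = table.sum(axis=0) / n
    ha = -np.sum(pa * np.log(pa))
    hb = -np.sum(pb * np.log(pb))
    if ha == 0 or hb == 0:
        if _same_partition(a, b):
            return 1.0
        raise DegeneratePartitionError(
            "NMI undefined: a partition with a single cluster"
        )
    pij = table / n
    nz = pij > 0
    mi = np.sum(pij[nz] * np.log(pij[nz] / (np.outer(pa, pb)[nz])))
    return float(np.clip(mi / np.sqrt(ha * hb), 0.0, 1.0))


@dataclass(frozen=True)
class MarkerResult:
    """Markers of one view: the union set plus the per-cluster table."""

    genes: frozenset
    table: pd.DataFrame = field(repr=False)
    alpha: float = 0.05
    min_abs_effect: float = 0.25


def find_markers(
    view_reconstruction: np.ndarray,
    gene_ids,
    labels,
    alpha: float = 0.05,
    min_abs_effect: float = 0.25,
    exclude: np.ndarray | None = None,
) -> MarkerResult:
    """Detect marker genes of a clustered view.

    Parameters
    ----------
    view_reconstruction : (n_genes, n_cells) array
        Gene-level component reconstruction (may contain negative
        values; the rank-sum test is location-based).
    gene_ids : sequence of str
    labels : array or ClusterAssignment
        Cluster label per cell; at least two non-empty clusters.
    exclude : boolean array, optional
        Genes to skip (e.g. zero pad rows).

    Returns the union of per-cluster marker sets and a long-format table
    (gene, cluster, mean_diff, p, p_adj, marker).
    """
    X = np.asarray(view_reconstruction, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    lab = _labels(labels)
    if X.shape[1] != lab.size:
        raise ValueError("cell count of matrix and labels differ")
    clusters = np.unique(lab)
    if clusters.size < 2:
        raise ValueError("marker detection needs at least 2 clusters")
    keep = np.ones(X.shape[0], dtype=bool) if exclude is None else ~np.asarray(exclude, bool)
    Xk, ids = X[keep], gene_ids[keep]
    rows = []
    for c in clusters:
        inc = lab == c
        if inc.sum() == 0 or (~inc).sum() == 0:
            raise ValueError(f"cluster {c} is empty or spans all cells")
        x_in, x_out = Xk[:, inc], Xk[:, ~inc]
        res = scipy.stats.mannwhitneyu(x_in, x_out, axis=1, alternative="two-sided")
        p = np.asarray(res.pvalue)
        diff = x_in.mean(axis=1) - x_out.mean(axis=1)
        p_adj = multipletests(p, method="fdr_bh")[1]
        marker = (p_adj <= alpha) & (np.abs(diff) >= min_abs_effect)
        rows.append(pd.DataFrame({
            "gene": ids, "cluster": c, "mean_diff": diff,
            "p": p, "p_adj": p_adj, "marker": marker,
        }))
    table = pd.concat(rows, ignore_index=True)
    genes = frozenset(table.loc[table["marker"], "gene"])
    return MarkerResult(genes, table, alpha, min_abs_effect)


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered marker sets G_0..G_M (original, approx, detail views)."""

    sets: tuple
    universe: frozenset
    view_labels: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "sets", tuple(frozenset(s) for s in self.sets))
        object.__setattr__(self, "universe", frozenset(self.universe))
        for i, s in enumerate(self.sets):
            if not s <= self.universe:
                raise ValueError(f"set {i} contains genes outside the universe")
        if not self.view_labels:
            labels = ["original", "approx"] + [
                f"detail-{j}" for j in range(1, len(self.sets) - 1)
            ]
            object.__setattr__(self, "view_labels", tuple(labels[: len(self.sets)]))


@dataclass(frozen=True)
class IntersectionReport:
    """Exclusive intersection cells N_L over all non-empty subsets L."""

    entries: dict = field(repr=False)  # frozenset(L) -> frozenset of genes
    set_sizes: tuple
    view_labels: tuple

    def size(self, L) -> int:
        return len(self.entries[frozenset(L)])

    @property
    def leakage(self) -> int:
        """Total genes in cells with |L| >= 2 that exclude view 0.

        Orthogonality of the wavelet components predicts these
        cross-component cells stay small; reported as a diagnostic,
        never asserted.
        """
        return sum(
            len(g) for L, g in self.entries.items() if len(L) >= 2 and 0 not in L
        )

    def to_frame(self) -> pd.DataFrame:
        m = len(self.view_labels)
        rows = []
        for L in sorted(self.entries, key=lambda s: (len(s), sorted(s))):
            genes = self.entries[L]
            rows.append({
                "subset": "{" + ",".join(str(i) for i in sorted(L)) + "}",
                "mask": "".join("1" if i in L else "0" for i in range(m)),
                "views": "&".join(self.view_labels[i] for i in sorted(L)),
                "size": len(genes),
                "genes": ";".join(sorted(genes)),
            })
        return pd.DataFrame(rows)


def intersection_analysis(G: GeneSetCollection) -> IntersectionReport:
    """Partition the union of marker sets into exclusive cells N_L.

    For every non-empty subset L of view indices, N_L holds the genes
    in all sets of L and in no other set; the cells are pairwise
    disjoint and their sizes sum to the size of the union.
    """
    m = len(G.sets)
    entries = {
        frozenset(L): set()
        for r in range(1, m + 1)
        for L in itertools.combinations(range(m), r)
    }
    union = frozenset().union(*G.sets) if G.sets else frozenset()
    for gene in union:
        L = frozenset(i for i, s in enumerate(G.sets) if gene in s)
        entries[L].add(gene)
    entries = {L: frozenset(g) for L, g in entries.items()}
    return IntersectionReport(
        entries=entries,
        set_sizes=tuple(len(s) for s in G.sets),
        view_labels=G.view_labels,
    )


@dataclass(frozen=True)
class ConcordanceReport:
    """Pairwise ARI/NMI between views, averaged over replicates."""

    table: pd.DataFrame = field(repr=False)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def pairwise_concordance(
    assignments_per_replicate,
    include_original: bool = True,
) -> ConcordanceReport:
    """Average pairwise ARI/NMI over replicate multi-view clusterings.

    Parameters
    ----------
    assignments_per_replicate : sequence of dict
        One dict per replicate mapping view label -> labels /
        ClusterAssignment.  A single dict is accepted for one replicate.
    include_original : bool
        Whether pairs involving the untransformed original view are
        reported alongside the wavelet-component pairs.

    Degenerate pairs are recorded as NaN, not raised.
    """
    if isinstance(assignments_per_replicate, dict):
        assignments_per_replicate = [assignments_per_replicate]
    reps = list(assignments_per_replicate)
    views = list(reps[0].keys())
    if not include_original:
        views = [v for v in views if v != "original"]
    if len(views) < 2:
        raise ValueError("need at least 2 views for pairwise concordance")
    rows = []
    for vi, vj in itertools.combinations(views, 2):
        aris, nmis = [], []
        for rep in reps:
            for fn, acc in ((ari, aris), (nmi, nmis)):
                try:
                    acc.append(fn(rep[vi], rep[vj]))
                except DegeneratePartitionError:
                    acc.append(np.nan)
        rows.append({
            "view_i": vi, "view_j": vj,
            "ARI": float(np.nanmean(aris)) if not np.all(np.isnan(aris)) else np.nan,
            "NMI": float(np.nanmean(nmis)) if not np.all(np.isnan(nmis)) else np.nan,
            "n_replicates": len(reps),
        })
    return ConcordanceReport(pd.DataFrame(rows))
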