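"""Per-pair feature construction: statistical, graph-theoretic, factor-based.

Each (disease i, metabolite j) pair gets the concatenation

* F1 (width ``2 * (2 + n_bins)``): known-association count (row/column sum of
  the association matrix), mean integrated similarity, and an ``n_bins``-bin
  histogram of the entity's integrated-similarity row, for the disease and the
  metabolite.
* F2 (width 10): degree, betweenness, closeness, eigenvector centrality and
  PageRank of the entity in the threshold graph of its integrated similarity
  matrix (edge iff similarity strictly exceeds the mean of all entries).
* F3 (width ``2k``): row i of the nonnegative factor A and column j of B from
  the rank-``k`` nonnegative matrix factorisation ``M ≈ A B``.

The assembled raw vectors are standardised and projected onto principal
components retaining a target fraction of variance; the projection is fit on
training pairs only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.decomposition import PCA

from .data_io import AssociationMatrix
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class ThresholdGraph:
    """Unweighted graph with an edge where similarity exceeds the global mean."""

    graph: nx.Graph
    threshold: float


@dataclass
class NmfFactors:
    """Nonnegative factors ``A (nd x k)``, ``B (k x nm)`` with error history."""

    A: np.ndarray
    B: np.ndarray
    k: int
    reconstruction_error: float
    error_history: list[float]


def statistical_features(
    m: AssociationMatrix,
    ids: SimilarityMatrix,
    ims: SimilarityMatrix,
    n_bins: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-entity F1 blocks: (disease block nd x (2 + n_bins), metabolite block).

    Histogram bins are equal-width on [0, 1] with a right-closed last bin; the
    proportions sum to 1 per entity (all-zero for an empty similarity row).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    d_block = _entity_stats(m.M.sum(axis=1), ids.values, n_bins)
    m_block = _entity_stats(m.M.sum(axis=0), ims.values, n_bins)
    return d_block, m_block


def _entity_stats(assoc_counts: np.ndarray, sim: np.ndarray, n_bins: int) -> np.ndarray:
    n = sim.shape[0]
    block = np.zeros((n, 2 + n_bins))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    for i in range(n):
        row = sim[i]
        block[i, 0] = assoc_counts[i]
        if row.size == 0:
            logger.info("empty similarity row for entity %d", i)
            continue
        block[i, 1] = row.mean()
        hist, _ = np.histogram(row, bins=edges)
        total = hist.sum()
        if total > 0:
            block[i, 2:] = hist / total
    return block


def build_threshold_graph(s: SimilarityMatrix, exclude_diagonal: bool = False) -> ThresholdGraph:
    """Edge (u, v), u != v, iff s(u, v) strictly exceeds the mean of all entries.

    The mean includes the diagonal by default (``exclude_diagonal`` drops it).
    """
    v = s.values
    n = v.shape[0]
    if exclude_diagonal and n > 1:
        threshold = float(v[~np.eye(n, dtype=bool)].mean())
    else:
        threshold = float(v.mean())
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    mask = v[iu, ju] > threshold
    g.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
    return ThresholdGraph(g, threshold)


def graph_features(tg: ThresholdGraph) -> np.ndarray:
    """Per-node F2 block: [degree, betweenness, closeness, eigenvector, PageRank].

    Isolated nodes get 0 for the three centralities; PageRank comes from the
    full damping-0.85 computation, so the vector over all nodes sums to 1.
    Eigenvector centrality is scale-normalised to unit maximum.
    """
    g = tg.graph
    n = g.number_of_nodes()
    block = np.zeros((n, 5))
    if n == 0:
        return block
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g)
    closeness = nx.closeness_centrality(g)
    if g.number_of_edges() > 0:
        # dominant adjacency eigenvector computed directly so disconnected
        # graphs are handled; scale-normalised to unit maximum
        adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
        eigvals, eigvecs = np.linalg.eigh(adj)
        vec = np.abs(eigvecs[:, -1])
        scale = vec.max()
        ordered = sorted(g.nodes)
        eig = {v: (vec[i] / scale if scale > 0 else 0.0) for i, v in enumerate(ordered)}
    else:
        eig = {v: 0.0 for v in g.nodes}
    pagerank = nx.pagerank(g, alpha=0.85, tol=1e-10, max_iter=1000)
    for node in g.nodes:
        block[node] = [degree[node], betweenness[node], closeness[node], eig[node], pagerank[node]]
    return block


def nmf_features(
    m: AssociationMatrix, k: int = 20, max_iter: int = 500, seed: int = 0, tol: float = 0.0
) -> NmfFactors:
    """Rank-``k`` NMF of the association matrix by multiplicative updates.

    Seeded nonnegative random initialisation; the Frobenius reconstruction
    error is recorded every 10 iterations and is non-increasing under the
    multiplicative-update rules.  The pair feature for (i, j) is row i of A
    concatenated with column j of B.
    """
    M = m.M
    nd, nm = M.shape
    if k > min(nd, nm):
        raise ValueError(f"rank k={k} exceeds min(n_diseases, n_metabolites)={min(nd, nm)}")
    if M.sum() == 0:
        raise ValueError("association matrix has no nonzero entries")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(M.mean() / k)
    A = scale * rng.random((nd, k)) + 1e-6
    B = scale * rng.random((k, nm)) + 1e-6
    eps = 1e-10
    history = [float(np.linalg.norm(M - A @ B))]
    for it in range(1, max_iter + 1):
        A *= (M @ B.T) / (A @ (B @ B.T) + eps)
        B *= (A.T @ M) / ((A.T @ A) @ B + eps)
        if it % 10 == 0 or it == max_iter:
            err = float(np.linalg.norm(M - A @ B))
            if tol > 0 and history and abs(history[-1] - err) < tol:
                history.append(err)
                break
            history.append(err)
    return NmfFactors(A, B, k, history[-1], history)


def pair_feature_matrix(
    pairs: np.ndarray,
    f1_d: np.ndarray,
    f1_m: np.ndarray,
    f2_d: np.ndarray,
    f2_m: np.ndarray,
    nmf: NmfFactors,
) -> np.ndarray:
    """Assemble raw F1 || F2 || F3 rows for (disease_idx, metabolite_idx) pairs."""
    di = pairs[:, 0]
    mj = pairs[:, 1]
    return np.hstack(
        [f1_d[di], f1_m[mj], f2_d[di], f2_m[mj], nmf.A[di], nmf.B[:, mj].T]
    )


@dataclass
class FeatureStage:
    """All per-entity blocks derived from one (possibly masked) matrix.

    Everything here depends on the association matrix, so cross-validation
    rebuilds the stage per fold from the masked matrix to avoid leakage.
    """

    f1_disease: np.ndarray
    f1_metabolite: np.ndarray
    f2_disease: np.ndarray
    f2_metabolite: np.ndarray
    nmf: NmfFactors
    ids: SimilarityMatrix
    ims: SimilarityMatrix

    def raw(self, pairs: np.ndarray) -> np.ndarray:
        return pair_feature_matrix(
            np.asarray(pairs, dtype=int),
            self.f1_disease,
            self.f1_metabolite,
            self.f2_disease,
            self.f2_metabolite,
            self.nmf,
        )

    @property
    def width(self) -> int:
        return (
            self.f1_disease.shape[1]
            + self.f1_metabolite.shape[1]
            + self.f2_disease.shape[1]
            + self.f2_metabolite.shape[1]
            + 2 * self.nmf.k
        )


def build_feature_stage(
    m: AssociationMatrix,
    ids: SimilarityMatrix,
    ims: SimilarityMatrix,
    n_bins: int = 5,
    nmf_rank: int = 20,
    nmf_max_iter: int = 500,
    nmf_seed: int = 0,
) -> FeatureStage:
    """Compute every per-entity feature block from one matrix + similarities."""
    f1_d, f1_m = statistical_features(m, ids, ims, n_bins)
    f2_d = graph_features(build_threshold_graph(ids))
    f2_m = graph_features(build_threshold_graph(ims))
    nmf = nmf_features(m, nmf_rank, nmf_max_iter, nmf_seed)
    return FeatureStage(f1_d, f1_m, f2_d, f2_m, nmf, ids, ims)


@dataclass
class FeatureReducer:
    """Standardisation + PCA projection fit on training pairs only."""

    keep_mask: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    pca: PCA

    def transform(self, raw: np.ndarray) -> np.ndarray:
        z = (raw[:, self.keep_mask] - self.mean) / self.std
        return self.pca.transform(z)


def fit_reducer(train_raw: np.ndarray, variance_kept: float = 0.95) -> FeatureReducer:
    """Drop constant columns, standardise, and fit PCA keeping ``variance_kept``.

    ``variance_kept >= 1`` keeps every component (full-rank rotation).
    """
    if not 0 < variance_kept <= 1:
        raise ValueError("variance_kept must lie in (0, 1]")
    std0 = train_raw.std(axis=0)
    keep = std0 > 1e-12
    if not keep.any():
        raise ValueError("all feature columns are constant")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d constant feature columns before PCA", n_dropped)
    mean = train_raw[:, keep].mean(axis=0)
    std = train_raw[:, keep].std(axis=0)
    z = (train_raw[:, keep] - mean) / std
    max_rank = min(z.shape)
    n_components: float | int = variance_kept if variance_kept < 1 else max_rank
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    pca.fit(z)
    return FeatureReducer(keep, mean, std, pca)
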