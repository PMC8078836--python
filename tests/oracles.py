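"""Independent brute-force oracles used to check the library implementations.

Everything here is deliberately written as plain loops over definitions, with
no reuse of the package's own code paths.
"""

from __future__ import annotations

import math

import numpy as np


# -- similarity ---------------------------------------------------------------


def hamming_similarity_oracle(MP: np.ndarray) -> np.ndarray:
    n_pathways, n_met = MP.shape
    out = np.zeros((n_met, n_met))
    for i in range(n_met):
        for j in range(n_met):
            mismatches = 0
            for k in range(n_pathways):
                if MP[k, i] != MP[k, j]:
                    mismatches += 1
            out[i, j] = 1.0 - mismatches / n_pathways
    return out


def entropy_oracle(counts: list[int], Tn: int) -> float:
    h = 0.0
    for n in counts:
        p = n / Tn
        h -= p * math.log2(p)
    return h


def nmi_similarity_oracle(
    symptoms: dict[str, dict[str, int]], disease_ids: list[str], shared: str = "min"
) -> np.ndarray:
    Tn = sum(n for d in symptoms.values() for n in d.values())
    n = len(disease_ids)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            sa = symptoms.get(disease_ids[a], {})
            sb = symptoms.get(disease_ids[b], {})
            if a == b:
                out[a, b] = 1.0 if sa else 0.0
                continue
            common = set(sa) & set(sb)
            ha = entropy_oracle(list(sa.values()), Tn) if sa else 0.0
            hb = entropy_oracle(list(sb.values()), Tn) if sb else 0.0
            if not common or ha + hb <= 0:
                continue
            if shared == "min":
                cts = [min(sa[s], sb[s]) for s in common]
            else:
                cts = [sa[s] + sb[s] for s in common]
            h_int = entropy_oracle(cts, Tn)
            out[a, b] = min(1.0, 2.0 * h_int / (ha + hb))
    return out


def gip_similarity_oracle(profiles: np.ndarray, omega_prime: float = 1.0) -> np.ndarray:
    n = profiles.shape[0]
    mean_sq = sum(float(profiles[i] @ profiles[i]) for i in range(n)) / n
    omega = omega_prime / mean_sq
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2 = float((profiles[i] - profiles[j]) @ (profiles[i] - profiles[j]))
            out[i, j] = math.exp(-omega * d2)
    return out


def integrate_oracle(primary: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    out = np.zeros_like(primary)
    for i in range(primary.shape[0]):
        for j in range(primary.shape[1]):
            out[i, j] = primary[i, j] if primary[i, j] != 0 else fallback[i, j]
    return out


# -- GOSS ---------------------------------------------------------------------


def exact_variance_gain(gradients: np.ndarray, values: np.ndarray, d: float) -> float:
    """All-data split variance gain: (1/n)[(sum g_l)^2/n_l + (sum g_r)^2/n_r]."""
    n = len(gradients)
    left = [g for g, v in zip(gradients, values) if v <= d]
    right = [g for g, v in zip(gradients, values) if v > d]
    if not left or not right:
        return float("-inf")
    return (sum(left) ** 2 / len(left) + sum(right) ** 2 / len(right)) / n


def goss_gain_oracle(
    kept: np.ndarray,
    sampled: np.ndarray,
    amplifier: float,
    gradients: np.ndarray,
    values: np.ndarray,
    d: float,
) -> float:
    """Term-by-term evaluation of the estimated variance gain."""
    a_l = [i for i in kept if values[i] <= d]
    a_r = [i for i in kept if values[i] > d]
    b_l = [i for i in sampled if values[i] <= d]
    b_r = [i for i in sampled if values[i] > d]
    n_l = len(a_l) + len(b_l)
    n_r = len(a_r) + len(b_r)
    if n_l == 0 or n_r == 0:
        return float("-inf")
    s_l = sum(gradients[i] for i in a_l) + amplifier * sum(gradients[i] for i in b_l)
    s_r = sum(gradients[i] for i in a_r) + amplifier * sum(gradients[i] for i in b_r)
    n = len(kept) + len(sampled)
    return (s_l**2 / n_l + s_r**2 / n_r) / n


def pairwise_conflicts(feature_matrix: np.ndarray, members: list[int]) -> int:
    """Exhaustive conflict count within one bundle."""
    total = 0
    for ai in range(len(members)):
        for bi in range(ai + 1, len(members)):
            for row in range(feature_matrix.shape[0]):
                if feature_matrix[row, members[ai]] != 0 and feature_matrix[row, members[bi]] != 0:
                    total += 1
    return total


# -- graph centralities -------------------------------------------------------


def _all_shortest_paths(adj: dict[int, set[int]], nodes: list[int]):
    """BFS shortest-path counts and distances from every source."""
    dist = {}
    sigma = {}
    preds = {}
    for s in nodes:
        d = {s: 0}
        sig = {s: 1.0}
        pred: dict[int, list[int]] = {s: []}
        queue = [s]
        while queue:
            u = queue.pop(0)
            for v in adj[u]:
                if v not in d:
                    d[v] = d[u] + 1
                    sig[v] = 0.0
                    pred[v] = []
                    queue.append(v)
                if d[v] == d[u] + 1:
                    sig[v] += sig[u]
                    pred[v].append(u)
        dist[s] = d
        sigma[s] = sig
        preds[s] = pred
    return dist, sigma, preds


def betweenness_oracle(adj: dict[int, set[int]], nodes: list[int]) -> dict[int, float]:
    """Pair-dependency accumulation over enumerated shortest paths (normalised)."""
    dist, sigma, preds = _all_shortest_paths(adj, nodes)
    bc = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t or t not in dist[s]:
                continue
            # fraction of s-t shortest paths through each v, by recursive path counts
            for v in nodes:
                if v in (s, t) or v not in dist[s]:
                    continue
                if dist[s][v] + _safe_dist(dist, v, t) == dist[s][t]:
                    bc[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    n = len(nodes)
    scale = (n - 1) * (n - 2) if n > 2 else 1
    return {v: bc[v] / scale for v in nodes}


def _safe_dist(dist, v, t):
    return dist[v].get(t, float("inf"))


def closeness_oracle(adj: dict[int, set[int]], nodes: list[int]) -> dict[int, float]:
    """Wasserman-Faust closeness with component-size correction."""
    dist, _, _ = _all_shortest_paths(adj, nodes)
    out = {}
    n = len(nodes)
    for v in nodes:
        reach = [d for u, d in dist[v].items() if u != v]
        if not reach:
            out[v] = 0.0
            continue
        total = sum(reach)
        out[v] = (len(reach) / total) * (len(reach) / (n - 1))
    return out


def eigenvector_oracle(adj_matrix: np.ndarray, iters: int = 10000) -> np.ndarray:
    """Power iteration for the top-eigenvalue eigenvector, unit-max normalised.

    Iterates on the shifted matrix A + n I (same eigenvectors, all shifted
    eigenvalues positive) so bipartite components cannot make the iteration
    oscillate between the +lambda and -lambda eigenvectors.
    """
    n = adj_matrix.shape[0]
    shifted = adj_matrix + n * np.eye(n)
    x = np.ones(n)
    for _ in range(iters):
        x_new = shifted @ x
        norm = np.linalg.norm(x_new)
        if norm == 0:
            return np.zeros(n)
        x_new /= norm
        if np.linalg.norm(x_new - x) < 1e-14:
            x = x_new
            break
        x = x_new
    x = np.abs(x)
    return x / x.max() if x.max() > 0 else x


def pagerank_oracle(adj_matrix: np.ndarray, alpha: float = 0.85, iters: int = 10000) -> np.ndarray:
    """Power iteration with uniform teleport and dangling-mass redistribution."""
    n = adj_matrix.shape[0]
    deg = adj_matrix.sum(axis=1)
    p = np.full(n, 1.0 / n)
    for _ in range(iters):
        new = np.full(n, (1 - alpha) / n)
        dangling = p[deg == 0].sum()
        new += alpha * dangling / n
        for u in range(n):
            if deg[u] > 0:
                new += alpha * p[u] * adj_matrix[u] / deg[u]
        if np.abs(new - p).sum() < 1e-13:
            return new
        p = new
    return p


# -- misc ---------------------------------------------------------------------


def auc_enumeration_oracle(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def covariance_eigvals_oracle(X: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the (n-1)-denominator covariance matrix."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    return np.sort(np.linalg.eigvalsh(cov))[::-1]
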