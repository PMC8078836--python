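"""Gradient-based one-side sampling (GOSS) and exclusive feature bundling (EFB).

These are the two sampling/bundling primitives behind LightGBM-style gradient
boosting, implemented standalone so their semantics can be verified against
brute-force oracles:

* GOSS keeps the top ``a`` fraction of instances by absolute gradient and a
  uniform random ``b`` fraction of the rest, reweighting the sampled
  gradients by ``(1 - a) / b`` in the estimated variance gain

  ``V(d) = (1/n) [ (sum_{A_l} g + w sum_{B_l} g)^2 / n_l
                 + (sum_{A_r} g + w sum_{B_r} g)^2 / n_r ]``

  with left = values <= d, right = values > d, counted over the kept union.
* EFB greedily groups sparse features that are rarely simultaneously nonzero
  into bundles whose member value ranges are shifted to be disjoint, so one
  merged feature encodes them all.

The production classifier delegates tree training to LightGBM itself; this
module exists so the gain estimator and the bundling algorithms are directly
testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

NEG_INF = float("-inf")


@dataclass
class GradientSample:
    """Kept set A (top by |gradient|) and the random sample B of the rest.

    ``amplifier`` rescales gradient sums over B back to the size of the full
    complement ``A^c``; it equals ``(1 - a) / b`` under the fraction-of-total
    sampling convention (``|B| = b n``) and ``1 / b`` under the
    fraction-of-remainder convention (``|B| = b |A^c|``).
    """

    kept: np.ndarray
    sampled: np.ndarray
    a: float
    b: float
    n_total: int

    @property
    def amplifier(self) -> float:
        n_rest = self.n_total - self.kept.size
        return n_rest / self.sampled.size if self.sampled.size else 0.0

    @property
    def union(self) -> np.ndarray:
        return np.concatenate([self.kept, self.sampled])


@dataclass
class SplitEvaluation:
    """Estimated variance gain of splitting one feature at one point."""

    split_point: float
    gain: float
    n_left: int
    n_right: int


@dataclass
class FeatureBundle:
    """Features merged into one; offsets keep member value ranges disjoint."""

    member_features: list[int] = field(default_factory=list)
    offsets: list[float] = field(default_factory=list)
    conflict_count: int = 0


def goss_sample(
    gradients: np.ndarray,
    a: float,
    b: float,
    seed: int = 0,
    size_mode: str = "total",
) -> GradientSample:
    """Partition instances into the kept top-``a`` set and a sampled ``b`` set.

    ``|A| = ceil(a n)``; B is a uniform sample without replacement from the
    complement ``A^c``.  Two sizing conventions for ``b`` appear in
    descriptions of the algorithm: a fraction of the total instance count
    (``|B| = ceil(b n)``, the convention of the original algorithm, under
    which the gain amplifier is exactly ``(1 - a) / b``) and a fraction of the
    remainder (``|B| = ceil(b |A^c|)``, amplifier ``1 / b``).  The default is
    the fraction-of-total convention because it makes the variance-gain
    estimator consistent; ``size_mode="remainder"`` selects the other.  Ties
    in |gradient| break by ascending index.  Deterministic for a given seed.
    """
    gradients = np.asarray(gradients, dtype=float)
    n = gradients.size
    if not 0 < a <= 1:
        raise ValueError("a must lie in (0, 1]")
    if not 0 <= b <= 1:
        raise ValueError("b must lie in [0, 1]")
    n_keep = math.ceil(a * n)
    if n_keep < 1 and b == 0:
        raise ValueError("empty training subset: a*n < 1 and b = 0")
    # stable sort on (-|g|, index): ties keep ascending index order
    order = np.argsort(-np.abs(gradients), kind="stable")
    kept = np.sort(order[:n_keep])
    rest = np.sort(order[n_keep:])
    if size_mode == "total":
        n_sample = min(math.ceil(b * n), rest.size)
    elif size_mode == "remainder":
        n_sample = math.ceil(b * rest.size)
    else:
        raise ValueError(f"unknown size_mode {size_mode!r}")
    if n_sample > 0:
        rng = np.random.default_rng(seed)
        sampled = np.sort(rng.choice(rest, size=n_sample, replace=False))
    else:
        sampled = np.empty(0, dtype=kept.dtype)
    return GradientSample(kept, sampled, a, b, n)


def goss_variance_gain(
    sample: GradientSample,
    gradients: np.ndarray,
    feature_values: np.ndarray,
    d: float,
) -> SplitEvaluation:
    """Estimated variance gain of splitting ``feature_values <= d`` vs ``> d``.

    Counted over the kept union; an empty side yields a -inf sentinel gain.
    """
    gradients = np.asarray(gradients, dtype=float)
    feature_values = np.asarray(feature_values, dtype=float)
    w = sample.amplifier
    n = sample.kept.size + sample.sampled.size
    a_left = sample.kept[feature_values[sample.kept] <= d]
    a_right = sample.kept[feature_values[sample.kept] > d]
    b_left = sample.sampled[feature_values[sample.sampled] <= d]
    b_right = sample.sampled[feature_values[sample.sampled] > d]
    n_l = a_left.size + b_left.size
    n_r = a_right.size + b_right.size
    if n_l == 0 or n_r == 0:
        return SplitEvaluation(d, NEG_INF, n_l, n_r)
    left_sum = gradients[a_left].sum() + w * gradients[b_left].sum()
    right_sum = gradients[a_right].sum() + w * gradients[b_right].sum()
    gain = (left_sum**2 / n_l + right_sum**2 / n_r) / n
    return SplitEvaluation(d, float(gain), n_l, n_r)


def candidate_split_points(feature_values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct sorted feature values."""
    distinct = np.unique(np.asarray(feature_values, dtype=float))
    return (distinct[:-1] + distinct[1:]) / 2.0


def best_split(
    sample: GradientSample, gradients: np.ndarray, feature_values: np.ndarray
) -> SplitEvaluation:
    """Evaluate every candidate split point and return the highest gain."""
    best = SplitEvaluation(float("nan"), NEG_INF, 0, 0)
    for d in candidate_split_points(feature_values):
        ev = goss_variance_gain(sample, gradients, feature_values, d)
        if ev.gain > best.gain:
            best = ev
    return best


def _conflict_counts(feature_matrix: np.ndarray) -> np.ndarray:
    """Pairwise counts of rows where two features are simultaneously nonzero."""
    nz = (np.asarray(feature_matrix) != 0).astype(int)
    return nz.T @ nz


def greedy_bundle(feature_matrix: np.ndarray, max_conflicts: int = 0) -> list[FeatureBundle]:
    """Greedily assign features to bundles keeping total conflicts <= budget.

    Features are ordered by total conflict count descending; each is placed in
    the first existing bundle whose conflict total stays within
    ``max_conflicts``, else it opens a new bundle.  Conflicts are exact nonzero
    co-occurrence counts.
    """
    feature_matrix = np.asarray(feature_matrix)
    n_features = feature_matrix.shape[1]
    pair_conflicts = _conflict_counts(feature_matrix)
    np.fill_diagonal(pair_conflicts, 0)
    totals = pair_conflicts.sum(axis=0)
    order = sorted(range(n_features), key=lambda j: (-totals[j], j))
    bundles: list[FeatureBundle] = []
    for j in order:
        placed = False
        for bundle in bundles:
            added = int(sum(pair_conflicts[j, k] for k in bundle.member_features))
            if bundle.conflict_count + added <= max_conflicts:
                bundle.member_features.append(j)
                bundle.conflict_count += added
                placed = True
                break
        if not placed:
            bundles.append(FeatureBundle(member_features=[j]))
    for bundle in bundles:
        _assign_offsets(bundle, feature_matrix)
    return bundles


def _assign_offsets(bundle: FeatureBundle, feature_matrix: np.ndarray) -> None:
    """Cumulative offsets making member nonzero value ranges disjoint."""
    offsets = []
    total = 0.0
    for j in bundle.member_features:
        offsets.append(total)
        col = feature_matrix[:, j]
        total += float(col.max()) if col.size else 0.0
    bundle.offsets = offsets


def merge_exclusive_features(
    bundle: FeatureBundle, feature_matrix: np.ndarray
) -> tuple[np.ndarray, list[tuple[float, float, int]]]:
    """Merge a bundle's member columns into one offset-shifted feature.

    Per row the merged value is the offset-shifted value of the nonzero member
    (first by member order if several conflict); zero if all members are zero.
    The decode table of (range_low, range_high, feature_index] intervals
    inverts the mapping on conflict-free rows.
    """
    feature_matrix = np.asarray(feature_matrix, dtype=float)
    n_rows = feature_matrix.shape[0]
    merged = np.zeros(n_rows)
    for row in range(n_rows):
        for j, offset in zip(bundle.member_features, bundle.offsets):
            v = feature_matrix[row, j]
            if v != 0:
                merged[row] = offset + v
                break
    decode = [
        (offset, offset + float(feature_matrix[:, j].max()), j)
        for j, offset in zip(bundle.member_features, bundle.offsets)
    ]
    return merged, decode


def decode_merged(
    merged: np.ndarray, decode: list[tuple[float, float, int]], n_features: int
) -> np.ndarray:
    """Reconstruct the member columns of a bundle from its merged feature."""
    merged = np.asarray(merged, dtype=float)
    out = np.zeros((merged.size, n_features))
    for row, v in enumerate(merged):
        if v == 0:
            continue
        for low, high, j in decode:
            if low < v <= high:
                out[row, j] = v - low
                break
    return out
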