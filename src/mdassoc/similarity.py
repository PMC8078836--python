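"""Similarity matrices over diseases and metabolites.

Four base matrices and two integrated ones:

* ``MHS`` — metabolite Hamming similarity from shared pathway membership,
  ``MHS(i, j) = 1 - (# pathways where the two membership columns differ) / np``.
* ``DNF`` — disease functional similarity from symptom sets, a (non-standard)
  normalised mutual information ``2 H(Sa ∩ Sb) / (H(Sa) + H(Sb))`` where the
  entropy of a symptom set sums ``-p log2 p`` with global frequencies
  ``p = n / Tn``.
* ``DGS`` / ``MGS`` — Gaussian interaction-profile (GIP) kernels over the rows /
  columns of the association matrix, ``exp(-omega * ||V_i - V_j||^2)`` with the
  bandwidth normalised by the mean squared profile norm.
* ``IDS`` / ``IMS`` — integrated similarities: the functional value where it is
  nonzero, the GIP kernel value otherwise.

All six are symmetric and bounded in [0, 1]; the NMI can exceed 1 under its
global-frequency entropy and is clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_io import AssociationMatrix, PathwayMembership, SymptomCatalog

Axis = Literal["disease", "metabolite"]


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] over one entity axis."""

    values: np.ndarray
    axis: Axis
    kind: str
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square over its labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")


@dataclass
class GipBandwidth:
    """Normalised GIP kernel bandwidth ``omega = omega' / mean(||V_i||^2)``."""

    omega: float
    omega_prime: float
    axis: Axis


def metabolite_hamming_similarity(mp: PathwayMembership) -> SimilarityMatrix:
    """Hamming similarity between metabolite pathway-membership columns."""
    if mp.n_pathways < 1:
        raise ValueError("Hamming similarity needs at least one pathway")
    cols = mp.MP.T  # metabolites x pathways
    if cols.shape[0] == 1:
        values = np.ones((1, 1))
    else:
        values = 1.0 - squareform(pdist(cols, metric="hamming"))
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, "metabolite", "hamming", list(mp.metabolite_ids))


def symptom_entropy(disease: str, catalog: SymptomCatalog) -> float:
    """Information entropy of a disease's symptom set under global frequencies.

    ``H = -sum_i p_i log2 p_i`` with ``p_i = n_i / Tn``; an empty symptom set
    has entropy 0.
    """
    counts = catalog.symptom_set(disease)
    if not counts:
        return 0.0
    return _entropy_from_counts(list(counts.values()), catalog.Tn)


def _entropy_from_counts(counts: list[int], Tn: int) -> float:
    if Tn <= 0:
        raise ValueError("catalog total Tn must be positive")
    p = np.asarray(counts, dtype=float) / Tn
    return float(-(p * np.log2(p)).sum())


def disease_nmi_similarity(
    catalog: SymptomCatalog,
    disease_ids: list[str],
    shared_count: Literal["min", "sum"] = "min",
) -> SimilarityMatrix:
    """Symptom-set functional similarity ``2 H(Sa ∩ Sb) / (H(Sa) + H(Sb))``.

    A shared symptom's count in the intersection is the minimum of the two
    diseases' counts by default (``shared_count="sum"`` uses their sum).  Pairs
    with an empty intersection or zero entropy denominator get 0; values are
    clamped to [0, 1].  Self-similarity is 1 for diseases with a nonempty
    symptom set and 0 otherwise, so the GIP fallback covers symptomless
    diseases at integration time.
    """
    if catalog.Tn <= 0:
        raise ValueError("catalog total Tn must be positive")
    n = len(disease_ids)
    H = {d: symptom_entropy(d, catalog) for d in disease_ids}
    combine = min if shared_count == "min" else (lambda x, y: x + y)
    values = np.zeros((n, n))
    for a in range(n):
        sa = catalog.symptom_set(disease_ids[a])
        for b in range(a + 1, n):
            sb = catalog.symptom_set(disease_ids[b])
            shared = sa.keys() & sb.keys()
            denom = H[disease_ids[a]] + H[disease_ids[b]]
            if not shared or denom <= 0:
                continue
            h_int = _entropy_from_counts(
                [combine(sa[s], sb[s]) for s in shared], catalog.Tn
            )
            values[a, b] = values[b, a] = min(1.0, 2.0 * h_int / denom)
    for a in range(n):
        values[a, a] = 1.0 if catalog.symptom_set(disease_ids[a]) else 0.0
    return SimilarityMatrix(values, "disease", "nmi", list(disease_ids))


def gip_bandwidth(profiles: np.ndarray, omega_prime: float = 1.0, axis: Axis = "disease") -> GipBandwidth:
    """Normalise the raw bandwidth by the mean squared profile norm."""
    if omega_prime <= 0:
        raise ValueError("omega_prime must be positive")
    profiles = np.asarray(profiles, dtype=float)
    mean_sq = float((profiles**2).sum(axis=1).mean())
    if mean_sq == 0:
        raise ValueError("all interaction profiles are zero; bandwidth undefined")
    return GipBandwidth(omega_prime / mean_sq, omega_prime, axis)


def gip_similarity(
    m: AssociationMatrix, axis: Axis, omega_prime: float = 1.0
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over rows (disease) or columns."""
    if axis == "disease":
        profiles, labels = m.M, m.disease_ids
    elif axis == "metabolite":
        profiles, labels = m.M.T, m.metabolite_ids
    else:
        raise ValueError(f"unknown axis {axis!r}")
    bw = gip_bandwidth(profiles, omega_prime, axis)
    sq = squareform(pdist(profiles, metric="sqeuclidean")) if len(labels) > 1 else np.zeros((1, 1))
    values = np.exp(-bw.omega * sq)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, axis, "gip", list(labels))


def integrate_similarity(
    primary: SimilarityMatrix, fallback: SimilarityMatrix
) -> SimilarityMatrix:
    """Element-wise: primary where nonzero, else fallback."""
    if primary.axis != fallback.axis or primary.labels != fallback.labels:
        raise ValueError("cannot integrate similarity matrices over different entities")
    values = np.where(primary.values != 0, primary.values, fallback.values)
    return SimilarityMatrix(values, primary.axis, "integrated", list(primary.labels))


def integrated_similarities(
    m: AssociationMatrix,
    mp: PathwayMembership,
    catalog: SymptomCatalog,
    omega_prime_d: float = 1.0,
    omega_prime_m: float = 1.0,
    shared_count: Literal["min", "sum"] = "min",
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Build the integrated disease (IDS) and metabolite (IMS) matrices."""
    dnf = disease_nmi_similarity(catalog, m.disease_ids, shared_count)
    dgs = gip_similarity(m, "disease", omega_prime_d)
    mhs = metabolite_hamming_similarity(mp)
    mgs = gip_similarity(m, "metabolite", omega_prime_m)
    return integrate_similarity(dnf, dgs), integrate_similarity(mhs, mgs)
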