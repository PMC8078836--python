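"""Readers, writers and the index-aligned matrix containers.

Three tab-separated inputs drive the pipeline:

* disease-metabolite association pairs  -> :class:`AssociationMatrix`
* metabolite-pathway membership pairs   -> :class:`PathwayMembership`
* disease-symptom occurrence records    -> :class:`SymptomCatalog`

Labels are sorted lexicographically when a matrix is built, so matrix
orientation is deterministic across runs.  All files are UTF-8, tab-delimited,
with ``#`` comment lines permitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class AssociationMatrix:
    """Binary disease x metabolite incidence matrix with label registries.

    ``M[i, j] == 1`` iff disease ``disease_ids[i]`` is associated with
    metabolite ``metabolite_ids[j]``.
    """

    M: np.ndarray
    disease_ids: list[str]
    metabolite_ids: list[str]

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (len(self.disease_ids), len(self.metabolite_ids)):
            raise ValueError("matrix shape does not match label registries")
        if not np.isin(self.M, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        for labels, what in ((self.disease_ids, "disease"), (self.metabolite_ids, "metabolite")):
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate {what} labels")

    @property
    def n_diseases(self) -> int:
        return self.M.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.M.shape[1]

    def disease_index(self, disease_id: str) -> int:
        return self.disease_ids.index(disease_id)

    def pairs(self) -> list[tuple[str, str]]:
        """Emit the (disease_id, metabolite_id) pairs of the 1-entries."""
        di, mi = np.nonzero(self.M)
        return [(self.disease_ids[i], self.metabolite_ids[j]) for i, j in zip(di, mi)]

    def masked(self, pairs: Iterable[tuple[int, int]]) -> "AssociationMatrix":
        """Copy with the given (disease_index, metabolite_index) entries zeroed."""
        M = self.M.copy()
        for i, j in pairs:
            M[i, j] = 0.0
        return AssociationMatrix(M, self.disease_ids, self.metabolite_ids)


@dataclass
class PathwayMembership:
    """Binary pathway x metabolite membership matrix ``MP``."""

    MP: np.ndarray
    pathway_ids: list[str]
    metabolite_ids: list[str]

    def __post_init__(self) -> None:
        self.MP = np.asarray(self.MP, dtype=float)
        if self.MP.shape != (len(self.pathway_ids), len(self.metabolite_ids)):
            raise ValueError("matrix shape does not match label registries")
        if not np.isin(self.MP, (0.0, 1.0)).all():
            raise ValueError("membership entries must be 0 or 1")

    @property
    def n_pathways(self) -> int:
        return self.MP.shape[0]


@dataclass
class SymptomCatalog:
    """Per-disease symptom occurrence counts and the grand total ``Tn``.

    ``symptoms[d]`` maps each symptom id to its positive occurrence count for
    disease ``d``; ``Tn`` is the sum of all counts in the catalog and is the
    denominator of every symptom frequency.
    """

    symptoms: dict[str, dict[str, int]]
    Tn: int = field(init=False)

    def __post_init__(self) -> None:
        total = 0
        for disease, counts in self.symptoms.items():
            for symptom, n in counts.items():
                if n < 1:
                    raise ValueError(
                        f"symptom count must be >= 1 (disease {disease!r}, symptom {symptom!r})"
                    )
                total += n
        self.Tn = total

    def symptom_set(self, disease_id: str) -> dict[str, int]:
        return self.symptoms.get(disease_id, {})


def _read_table(path: str | Path, n_cols: int, what: str) -> list[list[str]]:
    """Read a TSV into rows of at least ``n_cols`` fields, skipping comments."""
    rows: list[list[str]] = []
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < n_cols:
                raise ValueError(
                    f"{path}:{lineno}: malformed {what} row, expected >= {n_cols} "
                    f"tab-separated fields, got {len(fields)}"
                )
            rows.append([f.strip() for f in fields])
    if not rows:
        raise ValueError(f"{path}: empty {what} file")
    return rows


def read_association_pairs(path: str | Path, header: bool = False) -> AssociationMatrix:
    """Read (disease_id, metabolite_id) pairs into an :class:`AssociationMatrix`.

    Duplicate pairs are collapsed (the association model is binary) with the
    collapsed count logged.  Labels are sorted lexicographically.
    """
    rows = _read_table(path, 2, "association")
    if header:
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: association file holds only a header")
    pairs = {(r[0], r[1]) for r in rows}
    n_dupes = len(rows) - len(pairs)
    if n_dupes:
        logger.info("collapsed %d duplicate association pairs", n_dupes)
    disease_ids = sorted({d for d, _ in pairs})
    metabolite_ids = sorted({m for _, m in pairs})
    d_idx = {d: i for i, d in enumerate(disease_ids)}
    m_idx = {m: j for j, m in enumerate(metabolite_ids)}
    M = np.zeros((len(disease_ids), len(metabolite_ids)))
    for d, m in pairs:
        M[d_idx[d], m_idx[m]] = 1.0
    return AssociationMatrix(M, disease_ids, metabolite_ids)


def read_pathway_membership(path: str | Path, metabolite_ids: list[str]) -> PathwayMembership:
    """Read (metabolite_id, pathway_id) pairs restricted to ``metabolite_ids``.

    Metabolites absent from the file get an all-zero column (logged); pathways
    whose every member is outside ``metabolite_ids`` are dropped.
    """
    rows = _read_table(path, 2, "pathway membership")
    keep = set(metabolite_ids)
    pairs = {(r[1], r[0]) for r in rows if r[0] in keep}  # (pathway, metabolite)
    if not pairs:
        raise ValueError(
            f"{path}: no overlap between file metabolites and the association matrix"
        )
    pathway_ids = sorted({p for p, _ in pairs})
    p_idx = {p: i for i, p in enumerate(pathway_ids)}
    m_idx = {m: j for j, m in enumerate(metabolite_ids)}
    MP = np.zeros((len(pathway_ids), len(metabolite_ids)))
    for p, m in pairs:
        MP[p_idx[p], m_idx[m]] = 1.0
    missing = [m for m in metabolite_ids if MP[:, m_idx[m]].sum() == 0]
    if missing:
        logger.info("%d metabolites have no pathway membership", len(missing))
    return PathwayMembership(MP, pathway_ids, list(metabolite_ids))


def read_symptom_catalog(path: str | Path, disease_ids: list[str]) -> SymptomCatalog:
    """Read (disease_id, symptom_id[, count]) records for ``disease_ids``.

    The count column is optional and defaults to 1; non-positive counts are an
    error.  Diseases absent from the file get empty symptom sets (logged).
    Records for diseases outside ``disease_ids`` are ignored.
    """
    rows = _read_table(path, 2, "symptom")
    keep = set(disease_ids)
    symptoms: dict[str, dict[str, int]] = {d: {} for d in disease_ids}
    for row in rows:
        disease, symptom = row[0], row[1]
        count = int(row[2]) if len(row) >= 3 and row[2] != "" else 1
        if count < 1:
            raise ValueError(f"non-positive symptom count {count} for ({disease}, {symptom})")
        if disease not in keep:
            continue
        symptoms[disease][symptom] = symptoms[disease].get(symptom, 0) + count
    empty = [d for d in disease_ids if not symptoms[d]]
    if empty:
        logger.info("%d diseases have no symptom records", len(empty))
    return SymptomCatalog(symptoms)


def write_predictions(scores: pd.DataFrame, path: str | Path, top_n: int | None = None) -> None:
    """Write ranked predictions as TSV.

    ``scores`` needs columns disease_id, metabolite_id, score, known_flag.
    Rows are sorted by descending score with lexicographic (disease_id,
    metabolite_id) tie-break; an explicit 1-based ``rank`` column is written.
    """
    ordered = scores.sort_values(
        ["score", "disease_id", "metabolite_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    if top_n is not None:
        ordered = ordered.head(top_n)
    out = ordered[["disease_id", "metabolite_id", "score", "known_flag"]].copy()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    out["score"] = out["score"].map(lambda s: f"{s:.10g}")
    out.to_csv(path, sep="\t", index=False)


def write_pairs(m: AssociationMatrix, path: str | Path) -> None:
    """Emit the association matrix back to a pair TSV (round-trip helper)."""
    with open(path, "w", encoding="utf-8") as fh:
        for d, met in sorted(m.pairs()):
            fh.write(f"{d}\t{met}\n")


def drop_profileless(
    m: AssociationMatrix, mp: PathwayMembership, catalog: SymptomCatalog
) -> tuple[AssociationMatrix, PathwayMembership, SymptomCatalog]:
    """Drop diseases with no symptoms and metabolites with no pathways.

    Mirrors corpus construction that keeps only entities with usable
    functional profiles; by default profileless entities are retained and
    covered by the interaction-profile kernel fallback instead.
    """
    keep_d = [i for i, d in enumerate(m.disease_ids) if catalog.symptom_set(d)]
    keep_m = [j for j in range(m.n_metabolites) if mp.MP[:, j].sum() > 0]
    if not keep_d or not keep_m:
        raise ValueError("dropping profileless entities would empty the matrix")
    m2 = AssociationMatrix(
        m.M[np.ix_(keep_d, keep_m)],
        [m.disease_ids[i] for i in keep_d],
        [m.metabolite_ids[j] for j in keep_m],
    )
    mp2 = PathwayMembership(mp.MP[:, keep_m], mp.pathway_ids, m2.metabolite_ids)
    cat2 = SymptomCatalog({d: dict(catalog.symptom_set(d)) for d in m2.disease_ids})
    return m2, mp2, cat2
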