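"""Model/Results interface over the full prediction pipeline.

:class:`MetaboliteDiseaseModel` bundles the three input tables (associations,
pathway memberships, symptom catalog) with a :class:`~mdassoc.model.ModelConfig`;
``fit()`` runs similarity construction, feature extraction, PCA, negative
sampling and classifier training, and returns an :class:`MDAResults` holding
the per-pair scores, ranking helpers and a ``summary()`` table.  Evaluation
protocols (leave-one-out and k-fold over the known positives) are methods of
the model because they retrain per fold on masked data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .data_io import (
    AssociationMatrix,
    PathwayMembership,
    SymptomCatalog,
    read_association_pairs,
    read_pathway_membership,
    read_symptom_catalog,
    write_predictions,
)
from .features import FeatureReducer, FeatureStage, build_feature_stage, fit_reducer
from .model import FittedScorer, ModelConfig, sample_negatives, score_all_pairs, train
from .similarity import integrated_similarities


def derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministically derive ``n`` stage seeds (< 2**31) from one seed."""
    return (np.random.SeedSequence(seed).generate_state(n) % (2**31)).tolist()


@dataclass
class MDADataset:
    """The three aligned inputs of one study."""

    associations: AssociationMatrix
    pathways: PathwayMembership
    symptoms: SymptomCatalog

    def __post_init__(self) -> None:
        if self.pathways.metabolite_ids != self.associations.metabolite_ids:
            raise ValueError("pathway membership is not aligned with the association matrix")

    @classmethod
    def from_files(
        cls,
        association_path: str | Path,
        pathway_path: str | Path,
        symptom_path: str | Path,
    ) -> "MDADataset":
        m = read_association_pairs(association_path)
        mp = read_pathway_membership(pathway_path, m.metabolite_ids)
        catalog = read_symptom_catalog(symptom_path, m.disease_ids)
        return cls(m, mp, catalog)


class MetaboliteDiseaseModel:
    """Gradient-boosted ranking of candidate disease-metabolite pairs.

    Parameters
    ----------
    dataset:
        The aligned association matrix, pathway membership and symptom catalog.
    config:
        Classifier and feature hyperparameters; defaults are the tuned values.
    """

    def __init__(self, dataset: MDADataset, config: ModelConfig | None = None) -> None:
        self.dataset = dataset
        self.config = config or ModelConfig()

    @classmethod
    def from_tables(
        cls,
        association_path: str | Path,
        pathway_path: str | Path,
        symptom_path: str | Path,
        config: ModelConfig | None = None,
    ) -> "MetaboliteDiseaseModel":
        return cls(MDADataset.from_files(association_path, pathway_path, symptom_path), config)

    # -- feature pipeline -------------------------------------------------

    def feature_stage(self, m: AssociationMatrix | None = None, nmf_seed: int = 0) -> FeatureStage:
        """Build all per-entity feature blocks for a (possibly masked) matrix.

        Everything derived from the association matrix — the two GIP kernels,
        the integrated similarities, F1 counts and the NMF factors — is
        recomputed from the matrix passed here, so passing a masked matrix
        yields a leakage-free stage.
        """
        m = m if m is not None else self.dataset.associations
        c = self.config
        ids, ims = integrated_similarities(
            m, self.dataset.pathways, self.dataset.symptoms, c.omega_prime, c.omega_prime
        )
        return build_feature_stage(
            m, ids, ims, c.n_bins, c.nmf_rank, c.nmf_max_iter, nmf_seed
        )

    def all_pairs(self) -> np.ndarray:
        nd, nm = self.dataset.associations.M.shape
        di, mj = np.meshgrid(np.arange(nd), np.arange(nm), indexing="ij")
        return np.column_stack([di.ravel(), mj.ravel()])

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int | None = None) -> "MDAResults":
        """Train on all known positives + sampled negatives; score every pair."""
        seed = self.config.seed if seed is None else seed
        neg_seed, nmf_seed, clf_seed = derive_seeds(seed, 3)
        m = self.dataset.associations
        positives = np.column_stack(np.nonzero(m.M))
        negatives = sample_negatives(m, self.config.negative_ratio, neg_seed)
        stage = self.feature_stage(nmf_seed=nmf_seed)
        train_pairs = np.vstack([positives, negatives])
        labels = np.concatenate([np.ones(len(positives), int), np.zeros(len(negatives), int)])
        raw = stage.raw(train_pairs)
        reducer = fit_reducer(raw, self.config.variance_kept)
        clf_config = ModelConfig(**{**self.config.__dict__, "seed": clf_seed})
        scorer = train(reducer.transform(raw), labels, clf_config)
        pairs = self.all_pairs()
        scores = score_all_pairs(scorer, reducer.transform(stage.raw(pairs)))
        return MDAResults(self, stage, reducer, scorer, pairs, scores, seed)

    # -- evaluation protocols (retrain per fold on masked data) -------------

    def loocv(self, seed: int = 0, **kwargs):
        from .evaluation import loocv

        return loocv(self, seed=seed, **kwargs)

    def kfold_cv(self, k: int = 5, seed: int = 0, **kwargs):
        from .evaluation import kfold_cv

        return kfold_cv(self, k=k, seed=seed, **kwargs)


@dataclass
class MDAResults:
    """Fitted scores over every (disease, metabolite) pair plus diagnostics."""

    model: MetaboliteDiseaseModel
    stage: FeatureStage
    reducer: FeatureReducer
    scorer: FittedScorer
    pairs: np.ndarray
    scores: np.ndarray
    seed: int
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def frame(self) -> pd.DataFrame:
        """One row per pair: ids, score, known_flag."""
        if self._frame is None:
            m = self.model.dataset.associations
            self._frame = pd.DataFrame(
                {
                    "disease_id": [m.disease_ids[i] for i in self.pairs[:, 0]],
                    "metabolite_id": [m.metabolite_ids[j] for j in self.pairs[:, 1]],
                    "score": self.scores,
                    "known_flag": m.M[self.pairs[:, 0], self.pairs[:, 1]].astype(int),
                }
            )
        return self._frame

    def training_auc(self) -> float:
        """Rank AUC of known positives vs all unconfirmed pairs (resubstitution)."""
        from .evaluation import auc

        return auc(self.scores, self.frame["known_flag"].to_numpy())

    def rank_for_disease(self, disease_id: str, top_n: int = 10) -> pd.DataFrame:
        """Top unconfirmed metabolites for one disease, ranked by score."""
        m = self.model.dataset.associations
        if disease_id not in m.disease_ids:
            close = sorted(m.disease_ids, key=lambda d: _mismatch(d, disease_id))[:5]
            raise KeyError(f"unknown disease {disease_id!r}; nearest labels: {close}")
        sub = self.frame[
            (self.frame["disease_id"] == disease_id) & (self.frame["known_flag"] == 0)
        ]
        sub = sub.sort_values(
            ["score", "metabolite_id"], ascending=[False, True]
        ).reset_index(drop=True)
        sub.insert(0, "rank", np.arange(1, len(sub) + 1))
        return sub.head(top_n)

    def known_for_disease(self, disease_id: str) -> list[str]:
        m = self.model.dataset.associations
        i = m.disease_index(disease_id)
        return [m.metabolite_ids[j] for j in np.nonzero(m.M[i])[0]]

    def write_predictions(self, path: str | Path, top_n: int | None = None) -> None:
        write_predictions(self.frame, path, top_n)

    def provenance(self) -> dict:
        return {
            "package_version": _pkg_version,
            "seed": self.seed,
            "stage_seeds": derive_seeds(self.seed, 3),
            "config": self.model.config.__dict__,
            "n_diseases": self.model.dataset.associations.n_diseases,
            "n_metabolites": self.model.dataset.associations.n_metabolites,
            "n_positives": int(self.model.dataset.associations.M.sum()),
            "raw_feature_width": self.stage.width,
            "reduced_feature_width": int(self.reducer.pca.n_components_),
        }

    def summary(self) -> str:
        """Plain-text summary of the fitted run."""
        p = self.provenance()
        lines = [
            "Metabolite-disease association model",
            "=" * 44,
            f"diseases:            {p['n_diseases']}",
            f"metabolites:         {p['n_metabolites']}",
            f"known associations:  {p['n_positives']}",
            f"raw feature width:   {p['raw_feature_width']}",
            f"PCA components:      {p['reduced_feature_width']}"
            f" (variance kept >= {self.model.config.variance_kept})",
            f"classifier backend:  {self.scorer.backend}",
            f"trees / leaves:      {self.model.config.n_estimators} / {self.model.config.num_leaves}",
            f"resubstitution AUC:  {self.training_auc():.4f}",
            f"seed:                {self.seed}",
        ]
        return "\n".join(lines)


def _mismatch(a: str, b: str) -> int:
    """Cheap label distance for 'unknown id' suggestions."""
    return sum(x != y for x, y in zip(a, b)) + abs(len(a) - len(b))
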