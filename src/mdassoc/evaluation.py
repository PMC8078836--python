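"""Cross-validation protocols and ranking metrics.

Leave-one-out treats each known association in turn as the test case: the pair
is zeroed in the association matrix, every matrix-derived quantity (GIP
kernels, integrated similarities, degree statistics, NMF factors) is rebuilt
from the masked matrix, the classifier is retrained, and the held-out pair is
ranked against the unconfirmed metabolites of the same disease.  K-fold works
the same way on fold-sized groups of positives, with a held-out negative
sample of matching size as the test negatives.

AUC is the rank-based probability that a random positive outscores a random
negative, with ties counted 1/2 (the normalised Mann-Whitney U statistic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .core import MetaboliteDiseaseModel, derive_seeds
from .model import ModelConfig, sample_negatives, train


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def precision_recall_f1(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[float, float, float]:
    """Confusion-matrix metrics with predicted positive = score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes present")
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return precision, recall, f1


def top_k_hits(ranks: Sequence[int], ks: Sequence[int]) -> dict[int, int]:
    """Number of held-out positives ranked within the top k, per k."""
    ranks = np.asarray(list(ranks), dtype=int)
    return {int(k): int((ranks <= k).sum()) for k in ks}


@dataclass
class EvaluationReport:
    """Pooled metrics of one cross-validation run."""

    protocol: str
    auc: float
    precision: float
    recall: float
    f1: float
    roc_points: list[tuple[float, float]]
    per_fold_auc: list[float]
    top_k: dict[int, int]
    n_folds: int
    n_positives: int
    seed: int
    held_out_ranks: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["top_k"] = {str(k): v for k, v in payload["top_k"].items()}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def write_roc_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("fpr,tpr\n")
            for fpr, tpr in self.roc_points:
                fh.write(f"{fpr:.10g},{tpr:.10g}\n")


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> list[tuple[float, float]]:
    fpr, tpr, _ = roc_curve(labels, scores)
    pts = list(zip(fpr.tolist(), tpr.tolist()))
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def _fold_scorer(
    model: MetaboliteDiseaseModel,
    masked_pairs: list[tuple[int, int]],
    fold_seed: int,
    leakage_check: bool = True,
    fast_insecure: bool = False,
):
    """Retrain on a masked matrix; returns (scoring fn, stage, masked matrix).

    ``fast_insecure`` skips the per-fold feature recomputation and reuses the
    full-data stage (cheaper but leaky; provided for comparison only).
    """
    m = model.dataset.associations
    masked = m.masked(masked_pairs)
    neg_seed, nmf_seed, clf_seed = derive_seeds(fold_seed, 3)
    stage = model.feature_stage(m if fast_insecure else masked, nmf_seed=nmf_seed)
    if leakage_check and not fast_insecure:
        for i, j in masked_pairs:
            assert masked.M[i, j] == 0.0, "held-out pair leaked into the masked matrix"
            assert stage.f1_disease[i, 0] == masked.M[i].sum(), (
                "feature stage was not rebuilt from the masked matrix"
            )
    positives = np.column_stack(np.nonzero(masked.M))
    exclude = set(masked_pairs)
    negatives = sample_negatives(
        masked, model.config.negative_ratio, neg_seed, exclude=exclude
    )
    train_pairs = np.vstack([positives, negatives])
    labels = np.concatenate([np.ones(len(positives), int), np.zeros(len(negatives), int)])
    from .features import fit_reducer  # local to keep module import light

    raw = stage.raw(train_pairs)
    reducer = fit_reducer(raw, model.config.variance_kept)
    clf_config = ModelConfig(**{**model.config.__dict__, "seed": clf_seed})
    scorer = train(reducer.transform(raw), labels, clf_config)

    def score(pairs: np.ndarray) -> np.ndarray:
        return scorer.score(reducer.transform(stage.raw(np.asarray(pairs, dtype=int))))

    return score, negatives


def loocv(
    model: MetaboliteDiseaseModel,
    seed: int = 0,
    ks: Sequence[int] = (10, 20, 50, 100, 200),
    candidate_scope: str = "disease",
    fast_insecure: bool = False,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Leave-one-out over the known positives.

    Each positive is masked, the pipeline is rebuilt, and the held-out pair is
    scored against the unconfirmed pairs — by default those of the same
    disease (``candidate_scope="global"`` ranks against every unconfirmed
    pair).  Scores are pooled into one ROC/AUC; ``top_k`` counts how many
    held-out positives ranked within each k among their candidates.
    """
    m = model.dataset.associations
    positives = np.column_stack(np.nonzero(m.M))
    if len(positives) < 2:
        raise ValueError("leave-one-out needs at least two positives")
    fold_seeds = derive_seeds(seed, len(positives))
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    ranks: list[int] = []
    zero_pairs = np.column_stack(np.nonzero(m.M == 0))
    for fold, (i, j) in enumerate(positives):
        score, _ = _fold_scorer(
            model, [(int(i), int(j))], fold_seeds[fold], fast_insecure=fast_insecure
        )
        if candidate_scope == "disease":
            candidates = zero_pairs[zero_pairs[:, 0] == i]
        else:
            candidates = zero_pairs
        test_pairs = np.vstack([[i, j], candidates])
        s = score(test_pairs)
        labels = np.zeros(len(test_pairs), int)
        labels[0] = 1
        pooled_scores.append(s)
        pooled_labels.append(labels)
        # rank of the held-out pair among its candidates (1 = best; ties pessimistic)
        ranks.append(int(1 + (s[1:] >= s[0]).sum()))
    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    precision, recall, f1 = precision_recall_f1(scores, labels, threshold)
    return EvaluationReport(
        protocol="loocv",
        auc=auc(scores, labels),
        precision=precision,
        recall=recall,
        f1=f1,
        roc_points=_roc_points(scores, labels),
        per_fold_auc=[],
        top_k=top_k_hits(ranks, ks),
        n_folds=len(positives),
        n_positives=len(positives),
        seed=seed,
        held_out_ranks=ranks,
    )


def partition_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Random partition of range(n) into k folds with sizes differing by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k exceeds the number of positives")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(perm[f::k]) for f in range(k)]


def kfold_cv(
    model: MetaboliteDiseaseModel,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
    ks: Sequence[int] = (10, 20, 50, 100, 200),
    fast_insecure: bool = False,
) -> EvaluationReport:
    """K-fold cross-validation over the known positives.

    Each fold's positives are masked out of the matrix during feature
    construction and training, then each is ranked against the unconfirmed
    metabolites of its disease — the same candidate definition the
    leave-one-out protocol uses, so the two pooled AUCs are directly
    comparable.  Per-fold AUCs and the pooled ROC/AUC are reported.
    """
    m = model.dataset.associations
    positives = np.column_stack(np.nonzero(m.M))
    folds = partition_folds(len(positives), k, seed)
    fold_seeds = derive_seeds(seed + 1, k)
    zero_pairs = np.column_stack(np.nonzero(m.M == 0))
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    per_fold_auc: list[float] = []
    rank_in_fold: list[int] = []
    for f, fold_idx in enumerate(folds):
        held = positives[fold_idx]
        score, _ = _fold_scorer(
            model,
            [(int(i), int(j)) for i, j in held],
            fold_seeds[f],
            fast_insecure=fast_insecure,
        )
        fold_scores: list[np.ndarray] = []
        fold_labels: list[np.ndarray] = []
        for i, j in held:
            candidates = zero_pairs[zero_pairs[:, 0] == i]
            test_pairs = np.vstack([[i, j], candidates])
            s = score(test_pairs)
            lab = np.zeros(len(test_pairs), int)
            lab[0] = 1
            fold_scores.append(s)
            fold_labels.append(lab)
            rank_in_fold.append(int(1 + (s[1:] >= s[0]).sum()))
        fs = np.concatenate(fold_scores)
        fl = np.concatenate(fold_labels)
        per_fold_auc.append(auc(fs, fl))
        pooled_scores.append(fs)
        pooled_labels.append(fl)
    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    precision, recall, f1 = precision_recall_f1(scores, labels, threshold)
    return EvaluationReport(
        protocol="kfold",
        auc=auc(scores, labels),
        precision=precision,
        recall=recall,
        f1=f1,
        roc_points=_roc_points(scores, labels),
        per_fold_auc=per_fold_auc,
        top_k=top_k_hits(rank_in_fold, ks),
        n_folds=k,
        n_positives=len(positives),
        seed=seed,
        held_out_ranks=rank_in_fold,
    )


def grid_search(
    model: MetaboliteDiseaseModel,
    param_grid: dict[str, Sequence],
    k: int = 5,
    seed: int = 0,
) -> "pd.DataFrame":
    """Small k-fold sweep over classifier hyperparameters (one row per combo)."""
    import itertools

    import pandas as pd

    names = list(param_grid)
    rows = []
    for combo in itertools.product(*(param_grid[n] for n in names)):
        overrides = dict(zip(names, combo))
        cfg = ModelConfig(**{**model.config.__dict__, **overrides})
        swept = MetaboliteDiseaseModel(model.dataset, cfg)
        report = kfold_cv(swept, k=k, seed=seed)
        rows.append({**overrides, "auc": report.auc})
    return pd.DataFrame(rows)
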