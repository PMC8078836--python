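"""Training-set assembly and the gradient-boosted pair classifier.

Known associations are the positives; negatives are sampled uniformly from the
zero entries of the association matrix (the unconfirmed pairs), by default at
a 1:1 ratio.  The classifier is LightGBM with the tuned hyperparameters
(300 trees, depth 7, 15 leaves, 45 bins, 51 samples per leaf), run
single-threaded and deterministic; a pure scikit-learn histogram
gradient-boosting backend with the matching hyperparameters is selectable via
``ModelConfig.backend``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .data_io import AssociationMatrix


@dataclass
class ModelConfig:
    """Classifier and pipeline hyperparameters with the tuned defaults."""

    n_estimators: int = 300
    max_depth: int = 7
    num_leaves: int = 15
    max_bin: int = 45
    min_data_in_leaf: int = 51
    learning_rate: float = 0.1
    negative_ratio: float = 1.0
    seed: int = 0
    backend: str = "lightgbm"
    # feature-stage options
    n_bins: int = 5
    nmf_rank: int = 20
    nmf_max_iter: int = 500
    variance_kept: float = 0.95
    omega_prime: float = 1.0

    def __post_init__(self) -> None:
        if self.num_leaves > 2**self.max_depth:
            raise ValueError("num_leaves must not exceed 2**max_depth")
        for name in ("n_estimators", "max_depth", "num_leaves", "max_bin", "min_data_in_leaf"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConfig":
        """Load from JSON or simple ``key = value`` text."""
        text = Path(path).read_text(encoding="utf-8")
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = json.loads(value.strip())
        return cls(**data)


def sample_negatives(
    m: AssociationMatrix,
    ratio: float = 1.0,
    seed: int = 0,
    exclude: set[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Uniformly sample zero-entry (disease_idx, metabolite_idx) pairs.

    The sample size is ``ceil(ratio * positive count)``; it is disjoint from
    the positives and from ``exclude``, and deterministic per seed.
    """
    if ratio <= 0:
        raise ValueError("negative ratio must be positive")
    zero_d, zero_m = np.nonzero(m.M == 0)
    zeros = list(zip(zero_d.tolist(), zero_m.tolist()))
    if exclude:
        zeros = [p for p in zeros if p not in exclude]
    n_pos = int(m.M.sum())
    n_neg = math.ceil(ratio * n_pos)
    if n_neg > len(zeros):
        raise ValueError(
            f"requested {n_neg} negatives but only {len(zeros)} zero pairs are available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(zeros), size=n_neg, replace=False)
    return np.array([zeros[i] for i in sorted(chosen.tolist())], dtype=int)


@dataclass
class FittedScorer:
    """A trained classifier plus the feature width it expects."""

    estimator: object
    n_features: int
    backend: str

    def score(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.shape[1] != self.n_features:
            raise ValueError(
                f"feature width {features.shape[1]} does not match training width {self.n_features}"
            )
        with warnings.catch_warnings():
            # the LightGBM sklearn wrapper records internal feature names at
            # fit time, which makes sklearn's validation warn on ndarray input
            warnings.filterwarnings(
                "ignore", message="X does not have valid feature names"
            )
            return self.estimator.predict_proba(features)[:, 1]


def _make_estimator(config: ModelConfig):
    if config.backend == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            num_leaves=config.num_leaves,
            max_bin=config.max_bin,
            min_child_samples=config.min_data_in_leaf,
            learning_rate=config.learning_rate,
            random_state=config.seed,
            n_jobs=1,
            deterministic=True,
            force_row_wise=True,
            verbose=-1,
        )
    if config.backend == "sklearn":
        from sklearn.ensemble import HistGradientBoostingClassifier

        return HistGradientBoostingClassifier(
            max_iter=config.n_estimators,
            max_depth=config.max_depth,
            max_leaf_nodes=config.num_leaves,
            max_bins=min(config.max_bin, 255),
            min_samples_leaf=config.min_data_in_leaf,
            learning_rate=config.learning_rate,
            random_state=config.seed,
        )
    raise ValueError(f"unknown backend {config.backend!r}")


def train(features: np.ndarray, labels: np.ndarray, config: ModelConfig) -> FittedScorer:
    """Fit the binary pair classifier; scores land in [0, 1]."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    est = _make_estimator(config)
    est.fit(features, labels)
    return FittedScorer(est, features.shape[1], config.backend)


def score_all_pairs(scorer: FittedScorer, features: np.ndarray) -> np.ndarray:
    """Score every pair's feature row with the fitted classifier."""
    return scorer.score(features)
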