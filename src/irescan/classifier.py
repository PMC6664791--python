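"""Feature assembly, gradient-boosted training, evaluation, and prediction.

The model is a gradient-boosted decision-tree ensemble. Hyperparameters
use XGBoost-style names (eta, max_depth, min_child_weight, subsample,
colsample_bytree, n_rounds) and are mapped onto
:class:`sklearn.ensemble.GradientBoostingClassifier`:

    eta              -> learning_rate
    n_rounds         -> n_estimators
    max_depth        -> max_depth
    subsample        -> subsample
    colsample_bytree -> max_features (fraction)
    min_child_weight -> min_samples_leaf (leaf-size analogue)
    gamma/lambda/alpha have no direct analogue and are recorded only.

Defaults follow the published tuning: eta=0.01, max_depth=5,
min_child_weight=19, subsample=0.8, colsample_bytree=0.65, 1281 rounds.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier

from .errors import ConfigError, DegenerateInputError, SchemaError, ValidationError
from .kmer import (
    FeatureVector,
    KmerSpace,
    LocalWindowConfig,
    global_kmer_features,
    local_kmer_features,
)
from .sequence_io import RnaSequence
from .structure import FoldingEngine, structural_feature_vector

FEATURE_SELECTIONS = ("global-kmer", "local-kmer", "structural")


@dataclass(frozen=True)
class ModelConfig:
    """Gradient-boosting hyperparameters (XGBoost naming)."""

    eta: float = 0.01
    gamma: float = 0.0
    lambda_: float = 1.0
    alpha: float = 0.0
    max_depth: int = 5
    min_child_weight: int = 19
    subsample: float = 0.8
    colsample_bytree: float = 0.65
    n_rounds: int = 1281
    scale_pos_weight: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.eta <= 1):
            raise ConfigError("require 0 < eta <= 1")
        if not (0 < self.subsample <= 1 and 0 < self.colsample_bytree <= 1):
            raise ConfigError("subsample/colsample must be in (0, 1]")
        if self.max_depth < 1:
            raise ConfigError("max_depth must be >= 1")
        if self.n_rounds < 1:
            raise ConfigError("n_rounds must be >= 1")

    def to_sklearn(self) -> GradientBoostingClassifier:
        return GradientBoostingClassifier(
            learning_rate=self.eta,
            n_estimators=self.n_rounds,
            max_depth=self.max_depth,
            subsample=self.subsample,
            max_features=self.colsample_bytree,
            min_samples_leaf=self.min_child_weight,
            random_state=self.rng_seed,
        )


@dataclass
class TrainedModel:
    """A fitted ensemble plus everything needed to reuse it safely."""

    estimator: GradientBoostingClassifier
    feature_names: list[str]
    config: ModelConfig
    metadata: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return self.estimator.n_estimators_

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format": "irescan-model",
                "version": 1,
                "feature_names": self.feature_names,
                "config": asdict(self.config),
                "metadata": self.metadata,
                "estimator": self.estimator,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = joblib.load(path)
        if payload.get("format") != "irescan-model":
            raise ValidationError(f"{path} is not an irescan model container")
        return cls(
            estimator=payload["estimator"],
            feature_names=list(payload["feature_names"]),
            config=ModelConfig(**payload["config"]),
            metadata=dict(payload["metadata"]),
        )


@dataclass(frozen=True)
class EvaluationReport:
    auc_train: float
    auc_test: float
    threshold: float
    confusion: tuple[int, int, int, int]  # tn, fp, fn, tp
    per_fold: tuple[float, ...] = ()


def assemble_features(
    seqs: Sequence[RnaSequence],
    selection: Iterable[str] = ("global-kmer",),
    engine: FoldingEngine | None = None,
    n_shuffles: int = 100,
    rng_seed: int = 0,
    window_cfg: LocalWindowConfig | None = None,
    space: KmerSpace | None = None,
) -> pd.DataFrame:
    """Build the feature matrix (rows = sequences, named columns).

    Column blocks appear in the fixed order global-kmer, local-kmer,
    structural, regardless of the order given in ``selection``.
    """
    chosen = [s for s in FEATURE_SELECTIONS if s in set(selection)]
    unknown = set(selection) - set(FEATURE_SELECTIONS)
    if unknown:
        raise ConfigError(f"unknown feature selections: {sorted(unknown)}")
    if not chosen:
        raise ConfigError("feature selection must be non-empty")
    if "structural" in chosen and engine is None:
        raise ConfigError("structural features require a folding engine")
    space = space or KmerSpace()
    rows = []
    for i, seq in enumerate(seqs):
        parts: list[FeatureVector] = []
        if "global-kmer" in chosen:
            parts.append(global_kmer_features(seq, space))
        if "local-kmer" in chosen:
            parts.append(local_kmer_features(seq, space, window_cfg))
        if "structural" in chosen:
            parts.append(
                structural_feature_vector(
                    seq, engine, N=n_shuffles, rng_seed=rng_seed + i
                )
            )
        rows.append(FeatureVector.concat(*parts))
    names = list(rows[0].names) if rows else []
    matrix = np.vstack([r.values for r in rows]) if rows else np.empty((0, 0))
    index = [seq.id for seq in seqs]
    return pd.DataFrame(matrix, index=index, columns=names)


def split_train_validation(
    records: Sequence,
    fraction: float = 0.9,
    rng_seed: int = 0,
    labels: Sequence[int] | None = None,
    stratify: bool = False,
) -> tuple[list, list]:
    """Random disjoint/exhaustive split; train size is floor(fraction * n).

    With ``stratify`` the fraction is applied within each label class
    (labels required).
    """
    n = len(records)
    if n < 2:
        raise DegenerateInputError("need at least 2 records to split")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    if stratify:
        if labels is None:
            raise ConfigError("stratified split requires labels")
        labels = np.asarray(labels)
        train_idx: list[int] = []
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            train_idx.extend(idx[: math.floor(fraction * len(idx))])
        train_set = set(train_idx)
    else:
        order = rng.permutation(n)
        train_set = set(order[: math.floor(fraction * n)].tolist())
    train = [records[i] for i in range(n) if i in train_set]
    valid = [records[i] for i in range(n) if i not in train_set]
    return train, valid


def train(
    matrix: pd.DataFrame | np.ndarray,
    labels: Sequence[int],
    cfg: ModelConfig | None = None,
    feature_names: Sequence[str] | None = None,
    metadata: Mapping | None = None,
) -> TrainedModel:
    """Fit the gradient-boosted ensemble; deterministic given cfg.rng_seed."""
    cfg = cfg or ModelConfig()
    if isinstance(matrix, pd.DataFrame):
        feature_names = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        feature_names = list(feature_names or map(str, range(X.shape[1])))
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("feature/label length mismatch")
    if X.shape[0] < 2:
        raise DegenerateInputError("need at least 2 training rows")
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels contain a single class")
    est = cfg.to_sklearn()
    sample_weight = None
    if cfg.scale_pos_weight != 1.0:
        sample_weight = np.where(y == 1, cfg.scale_pos_weight, 1.0)
    est.fit(X, y, sample_weight=sample_weight)
    return TrainedModel(
        estimator=est,
        feature_names=feature_names,
        config=cfg,
        metadata=dict(metadata or {}),
    )


def predict(model: TrainedModel, matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """IRES probability per row; columns must match the training schema."""
    if isinstance(matrix, pd.DataFrame):
        cols = list(matrix.columns)
        if cols != model.feature_names:
            missing = [c for c in model.feature_names if c not in cols]
            extra = [c for c in cols if c not in model.feature_names]
            if missing or extra:
                raise SchemaError(missing, extra)
            matrix = matrix[model.feature_names]  # reorder only
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        if X.shape[1] != len(model.feature_names):
            raise SchemaError(model.feature_names[X.shape[1] :], [])
    return model.estimator.predict_proba(X)[:, 1]


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals (#{(pos, neg) pairs with score_pos > score_neg} + 0.5 * ties)
    / (n_pos * n_neg).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    # midranks handle ties exactly
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    rank_sum = ranks[y == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate(
    model: TrainedModel,
    train_matrix,
    train_labels,
    test_matrix,
    test_labels,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Train/test AUC plus a thresholded confusion count on the test set."""
    p_train = predict(model, train_matrix)
    p_test = predict(model, test_matrix)
    y = np.asarray(test_labels, dtype=int)
    calls = (p_test > threshold).astype(int)
    tp = int(((calls == 1) & (y == 1)).sum())
    tn = int(((calls == 0) & (y == 0)).sum())
    fp = int(((calls == 1) & (y == 0)).sum())
    fn = int(((calls == 0) & (y == 1)).sum())
    return EvaluationReport(
        auc_train=auc(train_labels, p_train),
        auc_test=auc(test_labels, p_test),
        threshold=threshold,
        confusion=(tn, fp, fn, tp),
    )


def kfold_indices(
    n: int, folds: int, rng_seed: int = 0
) -> list[np.ndarray]:
    """Disjoint, exhaustive, near-equal folds (sizes differ by <= 1)."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise DegenerateInputError("more folds than records")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(order, folds)]


DEFAULT_GRID: Mapping[str, Sequence] = {
    "eta": (0.01, 0.1),
    "max_depth": (3, 5),
    "subsample": (0.8,),
    "colsample_bytree": (0.65,),
}


def cross_validate_grid(
    matrix: pd.DataFrame | np.ndarray,
    labels: Sequence[int],
    grid: Mapping[str, Sequence] | None = None,
    folds: int = 10,
    rng_seed: int = 0,
    base_config: ModelConfig | None = None,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Grid search by k-fold cross validation, scored by mean held-out AUC.

    Every record is held out exactly once per parameter combination; the
    returned config is the combination with the highest mean AUC (first in
    grid order on ties). Intended for nested use on a training partition.
    """
    grid = dict(grid or DEFAULT_GRID)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ConfigError("grid must be non-empty")
    base = base_config or ModelConfig()
    X = (
        matrix.to_numpy(dtype=float)
        if isinstance(matrix, pd.DataFrame)
        else np.asarray(matrix, dtype=float)
    )
    y = np.asarray(labels, dtype=int)
    fold_idx = kfold_indices(len(y), folds, rng_seed)
    keys = list(grid)
    combos: list[dict] = [{}]
    for key in keys:
        combos = [{**c, key: v} for c in combos for v in grid[key]]
    rows = []
    best: tuple[float, int] | None = None
    for ci, combo in enumerate(combos):
        cfg = ModelConfig(**{**asdict(base), **combo})
        fold_scores = []
        for held_out in fold_idx:
            mask = np.ones(len(y), dtype=bool)
            mask[held_out] = False
            model = train(X[mask], y[mask], cfg)
            fold_scores.append(auc(y[~mask], predict(model, X[~mask])))
        mean_auc = float(np.mean(fold_scores))
        rows.append({**combo, "mean_auc": mean_auc})
        if best is None or mean_auc > best[0]:
            best = (mean_auc, ci)
    best_cfg = ModelConfig(**{**asdict(base), **combos[best[1]]})
    return best_cfg, pd.DataFrame(rows)


def feature_importance(
    model: TrainedModel, top_k: int | None = None
) -> list[tuple[str, float]]:
    """Features ranked by total split gain, descending; ties by name."""
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    gains = np.clip(model.estimator.feature_importances_, 0.0, None)
    ranked = sorted(
        zip(model.feature_names, gains), key=lambda kv: (-kv[1], kv[0])
    )
    return ranked[:top_k] if top_k else ranked
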