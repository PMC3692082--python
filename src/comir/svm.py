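"""Rank normalization and SVM integration of the four channel scores.

Channel scores live on incommensurable scales (expected occupied sites,
weighted site counts, summed regression scores), so the classifier never
sees raw scores: each channel is converted to a fractional rank over the
submitted gene universe, in [0, 1], with 1 the most target-like gene.
Rank normalization makes the integration invariant to any strictly
monotone rescaling of a channel and removes distributional differences
between species and miRNA sets.  A support vector machine trained on
labeled target/non-target genes maps the per-gene rank vector to a
probability of being a functional target of the miRNA set — the ComiR
score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .aggregate import ChannelScoreMatrix
from .io import Channel

__all__ = [
    "CHANNEL_DIRECTIONS",
    "rank_normalize",
    "features_from_block",
    "TrainedModel",
    "train_model",
    "predict",
    "save_model",
    "load_model",
    "ComirResult",
]

#: Which end of each channel's score scale is target-like.  Fermi-Dirac
#: occupancies and seed counts grow with targeting; mirSVR-type sums are
#: more negative for stronger predicted repression.
CHANNEL_DIRECTIONS: dict[str, str] = {
    Channel.MIRANDA_ENERGY.value: "higher_is_target",
    Channel.PITA_DDG.value: "higher_is_target",
    Channel.TARGETSCAN_SEED.value: "higher_is_target",
    Channel.MIRSVR.value: "lower_is_target",
}


def rank_normalize(
    scores: pd.Series, direction: str = "higher_is_target"
) -> pd.Series:
    """Fractional ranks r = rank / n with the most target-like gene at 1.

    Ties receive the average of their ranks; the result depends only on
    the ordering of the scores, so any strictly monotone transform of the
    input leaves it unchanged.  A constant input is flagged with a warning
    (every gene then gets (n + 1) / (2n)).
    """
    if direction not in ("higher_is_target", "lower_is_target"):
        raise ValueError(f"unknown direction {direction!r}")
    if len(scores) < 2:
        raise ValueError("rank normalization needs at least 2 genes")
    values = scores.to_numpy(dtype=float)
    if np.all(values == values[0]):
        warnings.warn(
            "all channel scores identical; fractional ranks carry no signal",
            stacklevel=2,
        )
    if direction == "lower_is_target":
        values = -values
    ranks = rankdata(values, method="average") / len(values)
    return pd.Series(ranks, index=scores.index, name=scores.name)


def features_from_block(
    block: pd.DataFrame,
    directions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Rank-normalize one label's genes x channels score block."""
    directions = dict(CHANNEL_DIRECTIONS if directions is None else directions)
    return pd.DataFrame(
        {ch: rank_normalize(block[ch], directions[ch]) for ch in block.columns},
        index=block.index,
    )


@dataclass
class TrainedModel:
    """A fitted SVM plus the metadata needed to apply it consistently."""

    estimator: CalibratedClassifierCV
    channels: tuple[str, ...]
    seed: int
    metadata: dict = field(default_factory=dict)

    def _check_features(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.channels if c not in features.columns]
        if missing:
            raise ValueError(f"features missing channel(s): {missing}")
        extra = [c for c in features.columns if c not in self.channels]
        if extra:
            raise ValueError(f"features carry unknown channel(s): {extra}")
        return features.loc[:, list(self.channels)].to_numpy(dtype=float)


def train_model(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    *,
    seed: int = 0,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: str | float = "scale",
    cv_folds: int = 5,
) -> TrainedModel:
    """Fit the probability-calibrated SVM on labeled rank features.

    ``labels`` is binary (1 = target, 0 = non-target); both classes must
    be present.  Probabilities come from the standard held-out Platt
    calibration performed during fitting.  Training is deterministic given
    the seed; the cross-validated AUROC is recorded in the model metadata.
    """
    y = np.asarray(labels).astype(int).ravel()
    if features.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = features.to_numpy(dtype=float)
    folds = min(cv_folds, int(np.bincount(y).min()))
    if folds < 2:
        raise ValueError("too few examples in the minority class to calibrate")
    svc = SVC(kernel=kernel, C=C, gamma=gamma, random_state=seed)
    clf = CalibratedClassifierCV(
        svc,
        method="sigmoid",
        cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed),
        ensemble=False,
    )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + 1)
    cv_auroc = float(np.mean(cross_val_score(clf, X, y, cv=skf, scoring="roc_auc")))
    clf.fit(X, y)
    return TrainedModel(
        estimator=clf,
        channels=tuple(str(c) for c in features.columns),
        seed=seed,
        metadata={
            "kernel": kernel,
            "C": C,
            "gamma": gamma,
            "cv_auroc": cv_auroc,
            "n_train": int(y.size),
            "class_balance": float(y.mean()),
        },
    )


@dataclass
class ComirResult:
    """Per-gene target probabilities, one column per label (sample/miRNA).

    ``ranks`` optionally carries the fractional rank of each gene's
    probability within each label; ``extra`` holds appended columns such
    as score differences and rank-sum p-values.
    """

    probabilities: pd.DataFrame
    ranks: pd.DataFrame | None = None
    extra: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        p = self.probabilities.to_numpy(dtype=float)
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.probabilities.index)

    @property
    def labels(self) -> list[str]:
        return [str(c) for c in self.probabilities.columns]

    def with_extra(self, name: str, values: pd.Series) -> "ComirResult":
        extra = pd.DataFrame(index=self.probabilities.index)
        if self.extra is not None:
            extra = self.extra.copy()
        extra[name] = values.reindex(self.probabilities.index)
        return ComirResult(self.probabilities, self.ranks, extra)

    def to_frame(self) -> pd.DataFrame:
        out = self.probabilities.copy()
        out.columns = [f"score_{c}" for c in out.columns]
        if self.ranks is not None:
            ranks = self.ranks.copy()
            ranks.columns = [f"rank_{c}" for c in ranks.columns]
            out = out.join(ranks)
        if self.extra is not None:
            out = out.join(self.extra)
        out.insert(0, "gene_id", out.index)
        return out.reset_index(drop=True)


def predict(
    model: TrainedModel, features: pd.DataFrame, label: str = "score"
) -> ComirResult:
    """Apply a trained model to rank features; returns one probability column."""
    X = model._check_features(features)
    proba = model.estimator.predict_proba(X)[:, list(model.estimator.classes_).index(1)]
    return ComirResult(
        probabilities=pd.DataFrame({label: proba}, index=features.index)
    )


def predict_matrix(
    model: TrainedModel,
    matrix: ChannelScoreMatrix,
    directions: Mapping[str, str] | None = None,
    *,
    with_ranks: bool = True,
) -> ComirResult:
    """Score every label of a channel matrix with one trained model."""
    probs: dict[str, np.ndarray] = {}
    for label in matrix.labels:
        feats = features_from_block(matrix.block(label), directions)
        probs[label] = predict(model, feats, label).probabilities[label].to_numpy()
    probabilities = pd.DataFrame(probs, index=matrix.scores.index)
    ranks = None
    if with_ranks:
        ranks = pd.DataFrame(
            {
                label: rank_normalize(probabilities[label], "higher_is_target")
                for label in probabilities.columns
            },
            index=probabilities.index,
        )
    return ComirResult(probabilities=probabilities, ranks=ranks)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model (joblib container, self-describing)."""
    joblib.dump(
        {
            "format": "comir-model",
            "version": 1,
            "estimator": model.estimator,
            "channels": model.channels,
            "seed": model.seed,
            "metadata": model.metadata,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format") != "comir-model":
        raise ValueError(f"{path}: not a comir model file")
    return TrainedModel(
        estimator=payload["estimator"],
        channels=tuple(payload["channels"]),
        seed=payload["seed"],
        metadata=payload["metadata"],
    )
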