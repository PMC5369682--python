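"""Voxelwise tumor likelihood P(f_i | Y_i).

The default classifier is a random forest with 200 trees trained on all
positive voxels and a 20% uniform subsample of the negatives (pooled across
the training cohort).  Any classifier implementing the small plug-in
contract below (fit rows, emit probabilities) can stand in — e.g. an
externally trained 3D CNN — without touching the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureStack


class VoxelClassifier:
    """Plug-in contract: fit on feature rows, emit P(tumor) per row."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "VoxelClassifier":  # pragma: no cover
        raise NotImplementedError

    def predict_proba_rows(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass
class ProbabilityMap:
    """Per-voxel tumor probability; zero outside the evaluation mask."""

    data: np.ndarray
    mask: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        inside = self.data[self.mask]
        if inside.size and (inside.min() < 0 or inside.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")


def sample_training_voxels(
    X: np.ndarray,
    y: np.ndarray,
    neg_fraction: float = 0.2,
    seed: int = 0,
) -> np.ndarray:
    """Indices keeping all positives and a uniform `neg_fraction` of negatives."""
    y = np.asarray(y).astype(bool)
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    if len(pos) == 0:
        raise ValueError("no positive voxels in the training cohort")
    n_neg = int(round(len(neg) * neg_fraction))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(neg, size=min(n_neg, len(neg)), replace=False) if n_neg else np.array([], int)
    return np.sort(np.concatenate([pos, chosen]))


@dataclass
class LikelihoodModel(VoxelClassifier):
    """Random-forest likelihood with order-checked feature columns."""

    n_trees: int = 200
    neg_fraction: float = 0.2
    seed: int = 0
    max_features: str | float = "sqrt"
    feature_names: tuple[str, ...] | None = None
    classifier: RandomForestClassifier | None = None
    training_log: dict = field(default_factory=dict)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LikelihoodModel":
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        self.classifier = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            bootstrap=True,
            oob_score=True,
            random_state=self.seed,
            n_jobs=1,
        )
        self.classifier.fit(X, y)
        self.training_log = {
            "seed": int(self.seed),
            "n_trees": int(self.n_trees),
            "n_samples": int(len(y)),
            "n_positive": int(y.sum()),
            "oob_score": float(self.classifier.oob_score_),
        }
        return self

    def predict_proba_rows(self, X: np.ndarray) -> np.ndarray:
        if self.classifier is None:
            raise RuntimeError("model is not fitted")
        if X.shape[0] == 0:
            return np.zeros(0)
        proba = self.classifier.predict_proba(X)
        pos_col = int(np.flatnonzero(self.classifier.classes_ == 1)[0])
        return proba[:, pos_col]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(
            {
                "version": 1,
                "n_trees": self.n_trees,
                "neg_fraction": self.neg_fraction,
                "seed": self.seed,
                "max_features": self.max_features,
                "feature_names": self.feature_names,
                "classifier": self.classifier,
                "training_log": self.training_log,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "LikelihoodModel":
        d = joblib.load(path)
        if d.get("version") != 1:
            raise ValueError("unsupported likelihood model container version")
        model = cls(
            n_trees=d["n_trees"],
            neg_fraction=d["neg_fraction"],
            seed=d["seed"],
            max_features=d["max_features"],
            feature_names=tuple(d["feature_names"]) if d["feature_names"] else None,
        )
        model.classifier = d["classifier"]
        model.training_log = d["training_log"]
        return model


def train_rf(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: tuple[str, ...],
    n_trees: int = 200,
    neg_fraction: float = 0.2,
    seed: int = 0,
) -> LikelihoodModel:
    """Subsample negatives, fit the forest, record the OOB score."""
    idx = sample_training_voxels(X, y, neg_fraction, seed)
    model = LikelihoodModel(
        n_trees=n_trees, neg_fraction=neg_fraction, seed=seed, feature_names=tuple(feature_names)
    )
    model.fit(X[idx], np.asarray(y)[idx])
    return model


def predict_proba(model: LikelihoodModel, stack: FeatureStack) -> ProbabilityMap:
    """Apply the likelihood inside the θ-band; outside voxels get 0."""
    if model.feature_names is not None and tuple(stack.feature_order) != tuple(model.feature_names):
        raise ValueError(
            f"feature column mismatch: model expects {model.feature_names}, "
            f"stack provides {stack.feature_order}"
        )
    data = np.zeros(stack.mask.shape)
    rows = stack.matrix()
    if rows.shape[0]:
        data[stack.mask] = model.predict_proba_rows(rows)
    return ProbabilityMap(data, stack.mask.copy(), stack.spacing.copy())
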