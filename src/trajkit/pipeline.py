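"""Analysis workflows: feature tables, classification, projection,
group comparison.

Two complementary workflows are supported.  The supervised one builds
a labeled feature table from simulated trajectories, trains a
diffusion-mode classifier and applies it to unseen data.  The
unsupervised one extracts the same features from unlabeled
(experimental) trajectories and compares feature distributions between
groups with a rank-based two-sample test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline as SkPipeline
from sklearn.preprocessing import StandardScaler

from .core import (
    DIFFUSION_LABELS,
    DegenerateTrajectoryError,
    SchemaError,
    Trajectory,
    TrajkitError,
    ValidationError,
)
from .features import FEATURE_NAMES, extract_all_features
from .io import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "build_feature_table",
    "ClassifierModel",
    "train_classifier",
    "classify",
    "Projection2D",
    "pca_projection",
    "compare_groups",
]

_MODEL_FORMAT_VERSION = 1


def build_feature_table(
    trajs: Iterable[Union[Trajectory, Tuple[Trajectory, Optional[str]]]],
) -> FeatureTable:
    """Extract all 17 features for each trajectory into one table.

    Accepts plain trajectories or ``(trajectory, label)`` pairs.  Rows
    whose feature extraction fails (e.g. constant trajectories) are
    excluded and logged with the failing feature; an error is raised
    only if every row fails.
    """
    items: List[Tuple[Trajectory, Optional[str]]] = []
    for entry in trajs:
        if isinstance(entry, Trajectory):
            items.append((entry, None))
        else:
            traj, label = entry
            items.append((traj, label))
    if not items:
        raise DegenerateTrajectoryError("no trajectories supplied")

    rows = []
    labels = []
    any_label = any(lab is not None for _, lab in items)
    for i, (traj, label) in enumerate(items):
        tid = traj.id if traj.id is not None else str(i)
        try:
            feats = extract_all_features(traj)
        except TrajkitError as exc:
            logger.warning("trajectory %s excluded: %s", tid, exc)
            continue
        rows.append({"id": tid, **feats})
        labels.append(label)
    if not rows:
        raise DegenerateTrajectoryError("feature extraction failed for every trajectory")
    df = pd.DataFrame(rows)
    if any_label:
        df["label"] = labels
    return FeatureTable(data=df)


# ---------------------------------------------------------------------------
# Classification


@dataclass
class ClassifierModel:
    """A fitted diffusion-mode classifier.

    Bundles the standardization + decision model pipeline with the
    feature vocabulary it was trained on, its class list, the values
    used to impute non-finite features (e.g. the fractal-dimension
    infinity sentinel) and training metadata.  Predicts only labels
    from its vocabulary and refuses tables whose feature names differ
    from the training features.
    """

    pipeline: SkPipeline = field(repr=False)
    feature_names: Tuple[str, ...]
    classes: Tuple[str, ...]
    cv_accuracy: float
    impute_values: Dict[str, float] = field(repr=False)
    metadata: Dict[str, object] = field(default_factory=dict)

    def save(self, path: Union[str, Path]) -> None:
        """Serialize to a single artifact file (format-versioned)."""
        joblib.dump(
            {
                "format_version": _MODEL_FORMAT_VERSION,
                "feature_names": self.feature_names,
                "classes": self.classes,
                "cv_accuracy": self.cv_accuracy,
                "impute_values": self.impute_values,
                "metadata": self.metadata,
                "pipeline": self.pipeline,
            },
            path,
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ClassifierModel":
        blob = joblib.load(path)
        if blob.get("format_version") != _MODEL_FORMAT_VERSION:
            raise SchemaError(
                f"unsupported model format version {blob.get('format_version')}"
            )
        return cls(
            pipeline=blob["pipeline"],
            feature_names=tuple(blob["feature_names"]),
            classes=tuple(blob["classes"]),
            cv_accuracy=float(blob["cv_accuracy"]),
            impute_values=dict(blob["impute_values"]),
            metadata=dict(blob["metadata"]),
        )


def _impute_matrix(X: np.ndarray, impute_values: Sequence[float]) -> np.ndarray:
    """Replace non-finite entries column-wise with the given values."""
    X = X.copy()
    for j, v in enumerate(impute_values):
        col = X[:, j]
        bad = ~np.isfinite(col)
        if bad.any():
            col[bad] = v
    return X


def _fit_impute_values(X: np.ndarray) -> List[float]:
    """Per-column imputation value: the maximum finite entry (0 if the
    whole column is non-finite).  Logged per affected column."""
    values = []
    for j in range(X.shape[1]):
        col = X[:, j]
        finite = col[np.isfinite(col)]
        v = float(finite.max()) if finite.size else 0.0
        if finite.size < col.size:
            logger.warning(
                "feature '%s': %d non-finite value(s) imputed to %g",
                FEATURE_NAMES[j], col.size - finite.size, v,
            )
        values.append(v)
    return values


def train_classifier(
    table: FeatureTable,
    seed: int = 0,
    n_estimators: int = 300,
) -> ClassifierModel:
    """Train a diffusion-mode classifier on a labeled feature table.

    Features are z-scored on the training data and fed to a
    random-forest ensemble; held-out accuracy is estimated by seeded
    stratified 5-fold cross-validation before refitting on the full
    table.  Requires >= 2 classes and >= 5 rows per class.
    """
    if not table.is_labeled:
        raise ValidationError("training requires a labeled feature table")
    y = np.asarray(table.labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("training requires at least 2 classes")
    if counts.min() < 5:
        raise ValidationError(
            f"training requires >= 5 rows per class (min seen: {counts.min()})"
        )
    X = table.feature_matrix()
    impute_values = _fit_impute_values(X)
    X = _impute_matrix(X, impute_values)

    pipe = SkPipeline(
        [
            ("scale", StandardScaler()),
            (
                "forest",
                RandomForestClassifier(n_estimators=n_estimators, random_state=seed),
            ),
        ]
    )
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    scores = cross_val_score(pipe, X, y, cv=cv, scoring="accuracy")
    pipe.fit(X, y)
    return ClassifierModel(
        pipeline=pipe,
        feature_names=FEATURE_NAMES,
        classes=tuple(str(c) for c in pipe.named_steps["forest"].classes_),
        cv_accuracy=float(scores.mean()),
        impute_values=dict(zip(FEATURE_NAMES, impute_values)),
        metadata={
            "seed": seed,
            "n_rows": int(len(table)),
            "n_per_class": {str(c): int(n) for c, n in zip(classes, counts)},
            "cv_fold_scores": [float(s) for s in scores],
        },
    )


def classify(model: ClassifierModel, table: FeatureTable) -> pd.DataFrame:
    """Predict the diffusion mode for every row of a feature table.

    Returns a data frame with ``id``, ``predicted`` and one probability
    column per class (rows sum to 1).
    """
    if tuple(table.feature_names) != tuple(model.feature_names):
        raise SchemaError(
            "feature names do not match the model's training features"
        )
    X = _impute_matrix(
        table.feature_matrix(), [model.impute_values[f] for f in model.feature_names]
    )
    pred = model.pipeline.predict(X)
    proba = model.pipeline.predict_proba(X)
    out = pd.DataFrame({"id": table.ids, "predicted": pred})
    for j, c in enumerate(model.classes):
        out[f"score_{c}"] = proba[:, j]
    return out


# ---------------------------------------------------------------------------
# Projection and group comparison


@dataclass(frozen=True)
class Projection2D:
    """Two-component principal-component scores of a feature table."""

    scores: np.ndarray  # (n_rows, 2)
    explained_variance_ratio: Tuple[float, float]


def pca_projection(table: FeatureTable) -> Projection2D:
    """Project z-scored features onto the top two principal components.

    Deterministic: component signs are fixed so the largest-magnitude
    loading of each component is positive.  Requires >= 3 rows and at
    least 2 features with nonzero variance.
    """
    if len(table) < 3:
        raise ValidationError("projection requires at least 3 rows")
    X = table.feature_matrix()
    X = _impute_matrix(X, _fit_impute_values(X))
    nonzero_var = (X.std(axis=0) > 0).sum()
    if nonzero_var < 2:
        raise ValidationError("projection requires >= 2 features with nonzero variance")
    Z = StandardScaler().fit_transform(X)
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(Z)
    for j in range(2):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, j] = -scores[:, j]
    evr = pca.explained_variance_ratio_
    return Projection2D(
        scores=scores, explained_variance_ratio=(float(evr[0]), float(evr[1]))
    )


def compare_groups(
    table_a: FeatureTable, table_b: FeatureTable, feature: str
) -> Dict[str, float]:
    """Two-sample comparison of one feature between two tables.

    Reports per-group mean and standard deviation, the mean difference
    (A minus B) and a two-sided Mann-Whitney U test; the rank-based
    test is the default because trajectory features are typically
    skewed.  Requires >= 3 rows per group.
    """
    for t in (table_a, table_b):
        if feature not in t.feature_names:
            raise SchemaError(f"feature '{feature}' not in table")
        if len(t) < 3:
            raise ValidationError("each group needs at least 3 rows")
    a = table_a.data[feature].to_numpy(dtype=float)
    b = table_b.data[feature].to_numpy(dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValidationError("each group needs at least 3 finite values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "feature": feature,
        "n_a": int(a.size),
        "n_b": int(b.size),
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
        "difference": float(a.mean() - b.mean()),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "test": "mannwhitneyu-two-sided",
    }
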