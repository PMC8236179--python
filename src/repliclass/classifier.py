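"""The random-forest plasmid/chromosome classifier.

A 500-tree forest (scikit-learn ``RandomForestClassifier``, impurity-based
splits, unbounded depth, sqrt(p) features per split) is trained on the
seven-feature table. A contig is called plasmid when the fraction of trees
voting plasmid strictly exceeds the decision threshold (default 0.5);
exactly at the threshold the call is chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ModelFormatError, ModelStateError, ValidationError
from .features import FEATURE_NAMES
from .sequence_io import CHROMOSOME, PLASMID

N_TREES_DEFAULT = 500
DECISION_THRESHOLD_DEFAULT = 0.5
FORMAT_VERSION = "repliclass-forest-1"


@dataclass
class ForestModel:
    """A trained forest plus the metadata needed to apply it safely."""

    n_trees: int = N_TREES_DEFAULT
    feature_names: tuple[str, ...] = FEATURE_NAMES
    decision_threshold: float = DECISION_THRESHOLD_DEFAULT
    training_seed: int = 0
    fitted: bool = False
    format_version: str = FORMAT_VERSION
    _estimator: RandomForestClassifier | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if not (0.0 < self.decision_threshold < 1.0):
            raise ValidationError("decision threshold must be in (0, 1)")

    @property
    def importances(self) -> dict[str, float]:
        return feature_importance(self)


def _validate_table(table: pd.DataFrame, feature_names: Sequence[str]) -> np.ndarray:
    missing = [name for name in feature_names if name not in table.columns]
    if missing:
        raise ValidationError(f"feature table is missing columns: {missing}")
    return table[list(feature_names)].to_numpy(dtype=float)


def train(
    features: pd.DataFrame,
    labels: Sequence[str],
    n_trees: int = N_TREES_DEFAULT,
    seed: int = 0,
    feature_names: Sequence[str] = FEATURE_NAMES,
    decision_threshold: float = DECISION_THRESHOLD_DEFAULT,
) -> ForestModel:
    """Fit the forest; reproducible given (features, labels, n_trees, seed)."""
    labels = list(labels)
    if len(labels) != len(features):
        raise ValidationError(
            f"{len(features)} feature rows but {len(labels)} labels"
        )
    bad = sorted({l for l in labels if l not in (PLASMID, CHROMOSOME)})
    if bad:
        raise ValidationError(f"labels must be plasmid/chromosome; got {bad}")
    if len(set(labels)) < 2:
        raise ValidationError("training requires both classes to be present")
    X = _validate_table(features, feature_names)
    y = np.array([1 if l == PLASMID else 0 for l in labels])
    estimator = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    estimator.fit(X, y)
    return ForestModel(
        n_trees=n_trees,
        feature_names=tuple(feature_names),
        decision_threshold=decision_threshold,
        training_seed=seed,
        fitted=True,
        _estimator=estimator,
    )


def predict(model: ForestModel, features: pd.DataFrame) -> pd.DataFrame:
    """Labels plus plasmid vote fractions, one row per feature row.

    Returns a frame with columns ``prediction`` and ``vote_fraction``
    indexed like ``features``; the label is plasmid iff the vote fraction
    strictly exceeds the model's decision threshold.
    """
    if not model.fitted or model._estimator is None:
        raise ModelStateError("model is not fitted")
    X = _validate_table(features, model.feature_names)
    plasmid_col = int(np.nonzero(model._estimator.classes_ == 1)[0][0])
    votes = model._estimator.predict_proba(X)[:, plasmid_col]
    labels = np.where(votes > model.decision_threshold, PLASMID, CHROMOSOME)
    return pd.DataFrame(
        {"prediction": labels, "vote_fraction": votes}, index=features.index
    )


def feature_importance(model: ForestModel) -> dict[str, float]:
    """Impurity-based (mean decrease in impurity) importances, summing to 1."""
    if not model.fitted or model._estimator is None:
        raise ModelStateError("model is not fitted")
    return dict(
        zip(model.feature_names, model._estimator.feature_importances_.tolist())
    )


def ablation_study(
    train_features: pd.DataFrame,
    train_labels: Sequence[str],
    test_features: pd.DataFrame,
    test_labels: Sequence[str],
    feature_subsets: Sequence[Iterable[str]],
    n_trees: int = N_TREES_DEFAULT,
    seed: int = 0,
) -> pd.DataFrame:
    """Train one model per feature subset and score each on the test rows.

    Returns one row per subset with the four performance indices and a
    ``best`` flag on the subset with the highest MCC (first wins on ties).
    """
    from .evaluation import confusion, metrics  # local import: avoid cycle

    reports = []
    for subset in feature_subsets:
        names = tuple(subset)
        if len(names) == 0:
            raise ValidationError("feature subset must be non-empty")
        unknown = [n for n in names if n not in FEATURE_NAMES]
        if unknown:
            raise ValidationError(f"unknown feature names: {unknown}")
        model = train(
            train_features, train_labels, n_trees=n_trees, seed=seed,
            feature_names=names,
        )
        pred = predict(model, test_features)
        truth = pd.Series(list(test_labels), index=test_features.index)
        report = metrics(confusion(pred["prediction"], truth))
        reports.append(
            {
                "features": "+".join(names),
                "n_features": len(names),
                "sensitivity": report.sensitivity,
                "precision": report.precision,
                "f1": report.f1,
                "mcc": report.mcc,
            }
        )
    table = pd.DataFrame(reports)
    mcc = table["mcc"].to_numpy(dtype=float)
    table["best"] = False
    table.loc[int(np.nanargmax(mcc)), "best"] = True
    return table


def save_model(model: ForestModel, path) -> None:
    """Persist a fitted model as a single-file artifact with metadata."""
    if not model.fitted or model._estimator is None:
        raise ModelStateError("refusing to save an unfitted model")
    payload = {
        "format_version": model.format_version,
        "n_trees": model.n_trees,
        "feature_names": list(model.feature_names),
        "decision_threshold": model.decision_threshold,
        "training_seed": model.training_seed,
        "estimator": model._estimator,
    }
    joblib.dump(payload, path)


def load_model(path) -> ForestModel:
    """Load a model written by :func:`save_model`; never mispredicts silently."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt/truncated pickle
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFormatError(f"{path} is not a repliclass model file")
    if payload["format_version"] != FORMAT_VERSION:
        raise ModelFormatError(
            f"model format {payload['format_version']!r} is incompatible with "
            f"this version ({FORMAT_VERSION!r})"
        )
    return ForestModel(
        n_trees=payload["n_trees"],
        feature_names=tuple(payload["feature_names"]),
        decision_threshold=payload["decision_threshold"],
        training_seed=payload["training_seed"],
        fitted=True,
        _estimator=payload["estimator"],
    )
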