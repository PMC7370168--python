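"""Organellar map visualization and marker-based localization prediction.

An organellar map is the set of per-protein 5-fraction abundance profiles
from one or more replicate fractionations.  Proteins of the same organelle
share a characteristic profile, so principal component analysis of the
profiles displays organelles as clusters, and a supervised classifier trained
on curated marker proteins transfers compartment labels to the rest of the
proteome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import f1_score, recall_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class MarkerSet:
    """Curated protein -> compartment assignments."""

    entries: pd.Series  # index protein_id, values compartment label

    def __post_init__(self) -> None:
        if self.entries.index.has_duplicates:
            dupes = self.entries.index[self.entries.index.duplicated()].unique()
            raise ValueError(f"markers assigned more than once: {list(dupes)[:5]}")
        counts = self.entries.value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"compartments with fewer than 2 markers: {list(small.index)}"
            )

    @property
    def compartments(self) -> list[str]:
        return sorted(self.entries.unique())

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path) -> "MarkerSet":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame.set_index(frame.columns[0])[frame.columns[1]])

    def to_tsv(self, path) -> None:
        self.entries.rename("compartment").rename_axis("protein_id").to_csv(
            path, sep="\t"
        )


def pca_map(
    profiles: pd.DataFrame,
    center: bool = True,
    unit_scale: bool = True,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project concatenated map profiles onto principal components.

    Matches the usual map visualization (``prcomp`` with ``center=TRUE,
    scale.=TRUE``): columns are centered and scaled to unit variance by
    default.  Zero-variance columns cannot be unit-scaled and are dropped
    with a warning.  Returns per-protein coordinates and the fraction of
    variance explained per component (non-increasing, summing to <= 1).
    """
    if profiles.shape[0] < 3 or profiles.shape[1] < 2:
        raise ValueError("need at least 3 proteins and 2 dimensions")
    X = profiles.to_numpy(dtype=float)
    keep = np.ones(X.shape[1], dtype=bool)
    if unit_scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance column(s) before scaling",
                stacklevel=2,
            )
        X = X[:, keep]
        sd = sd[keep]
        X = X / sd
    if center:
        X = X - X.mean(axis=0)
    n_components = min(n_components, min(X.shape) - (0 if center else 1))
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    frame = pd.DataFrame(
        coords,
        index=profiles.index,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return frame, pca.explained_variance_ratio_


DEFAULT_PARAM_GRID = {"C": [1.0, 10.0, 100.0], "gamma": ["scale", 1.0]}


def train_localization_classifier(
    profiles: pd.DataFrame,
    markers: MarkerSet,
    cv_folds: int = 5,
    seed: int = 0,
    param_grid: dict | None = None,
    margin: float = 0.1,
):
    """Train a compartment classifier on marker proteins.

    Input profiles should be the 0-1 normalized concatenation of the control
    replicate maps.  The model is a one-vs-rest RBF support vector machine
    with class-balanced weights; C and gamma are chosen by grid search inside
    a stratified cross-validation.  Reported metrics (per-class recall,
    overall recall, per-class F1, median F1) come from stratified
    cross-validated predictions on the markers only.

    Returns ``(model, metrics)``; the model carries the decision margin used
    by :func:`predict_localization` to leave low-confidence proteins
    unassigned.
    """
    common = markers.entries.index.intersection(profiles.index)
    missing = len(markers) - len(common)
    if missing:
        logger.info("%d markers not present in the profile set", missing)
    y = markers.entries.loc[common]
    counts = y.value_counts()
    small = counts[counts < cv_folds]
    if len(small):
        raise ValueError(
            f"compartments with fewer than cv_folds={cv_folds} markers: "
            f"{list(small.index)}"
        )
    X = profiles.loc[common].to_numpy(dtype=float)

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    base = SVC(
        kernel="rbf",
        class_weight="balanced",
        decision_function_shape="ovr",
        random_state=seed,
    )
    search = GridSearchCV(
        base, param_grid or DEFAULT_PARAM_GRID, cv=cv, scoring="balanced_accuracy"
    )
    search.fit(X, y)
    model = search.best_estimator_
    model.margin_ = margin
    model.feature_columns_ = list(profiles.columns)

    y_hat = cross_val_predict(model, X, y, cv=cv)
    labels = sorted(y.unique())
    per_class_recall = recall_score(y, y_hat, labels=labels, average=None)
    per_class_f1 = f1_score(y, y_hat, labels=labels, average=None)
    metrics = {
        "labels": labels,
        "per_class_recall": dict(zip(labels, per_class_recall.tolist())),
        "overall_recall": float((y_hat == y).mean()),
        "per_class_f1": dict(zip(labels, per_class_f1.tolist())),
        "median_f1": float(np.median(per_class_f1)),
        "best_params": search.best_params_,
    }
    return model, metrics


def predict_localization(
    model, profiles: pd.DataFrame, margin: float | None = None
) -> pd.DataFrame:
    """Assign compartments to profiles; ambiguous proteins stay unassigned.

    A protein is unassigned when the top one-vs-rest decision score exceeds
    the runner-up by less than ``margin`` (defaults to the margin stored at
    training time).
    """
    if list(profiles.columns) != getattr(model, "feature_columns_", list(profiles.columns)):
        raise ValueError("profile columns do not match the training dimensions")
    margin = model.margin_ if margin is None else margin
    X = profiles.to_numpy(dtype=float)
    scores = model.decision_function(X)
    if scores.ndim == 1:  # binary models return one column
        scores = np.column_stack([-scores, scores])
    order = np.argsort(scores, axis=1)
    top, second = order[:, -1], order[:, -2]
    gap = scores[np.arange(len(X)), top] - scores[np.arange(len(X)), second]
    predicted = model.classes_[top].astype(object)
    predicted[gap < margin] = UNASSIGNED
    out = pd.DataFrame(scores, index=profiles.index, columns=list(model.classes_))
    out.insert(0, "prediction", predicted)
    out.insert(1, "margin", gap)
    return out
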