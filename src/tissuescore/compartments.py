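"""Tumor-vs-stroma cell classification from analyst-circled regions.

An analyst circles small representative tumor and stroma areas; cells whose
centroids fall inside provide labeled feature rows; a supervised model
(random forest by default) learns the separation and is applied to every
cell, honoring inclusion/exclusion annotations with the total precedence
order exclude > train > include.  Point-in-polygon uses the cell centroid,
strictly inside on the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from skimage.draw import polygon2mask

from .config import FEATURE_COLUMNS, feature_hash
from .slideio import AnnotationSet


class FeatureHashError(ValueError):
    """Feature vector layout differs from the one the model was trained on."""


@dataclass
class CompartmentModel:
    classifier: object
    feature_hash: str
    n_train: dict
    heldout_accuracy: float
    family: str
    seed: int

    def predict(self, cells: pd.DataFrame) -> np.ndarray:
        if feature_hash() != self.feature_hash:
            raise FeatureHashError(
                "feature order hash mismatch; retrain the model")
        return self.classifier.predict(cells[list(FEATURE_COLUMNS)].to_numpy())

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "CompartmentModel":
        return joblib.load(path)


def _poly(ring: np.ndarray) -> Polygon:
    return Polygon(np.asarray(ring, dtype=float))


def points_in_polygons(x, y, rings) -> np.ndarray:
    """True where (x, y) is strictly inside any of the polygon rings."""
    inside = np.zeros(len(x), dtype=bool)
    for ring in rings:
        inside |= shapely.contains_xy(_poly(ring), x, y)
    return inside


def rasterize_roles(annotations: AnnotationSet, shape) -> tuple:
    """(include, exclude) boolean masks; empty include list = whole frame."""
    include_rings = annotations.by_role("include") if annotations else []
    exclude_rings = annotations.by_role("exclude") if annotations else []
    if include_rings:
        include = np.zeros(shape, bool)
        for ring in include_rings:
            include |= polygon2mask(shape, np.asarray(ring)[:, ::-1])
    else:
        include = np.ones(shape, bool)
    exclude = np.zeros(shape, bool)
    for ring in exclude_rings:
        exclude |= polygon2mask(shape, np.asarray(ring)[:, ::-1])
    return include, exclude


def harvest_training_cells(cells: pd.DataFrame, annotations: AnnotationSet
                           ) -> pd.DataFrame:
    """Label cells inside training polygons; exclusion wins over training."""
    t_rings = annotations.by_role("train_tumor")
    s_rings = annotations.by_role("train_stroma")
    if not t_rings or not s_rings:
        raise ValueError(
            "need at least one train_tumor and one train_stroma polygon")
    x = cells.x.to_numpy()
    y = cells.y.to_numpy()
    in_t = points_in_polygons(x, y, t_rings)
    in_s = points_in_polygons(x, y, s_rings)
    in_x = points_in_polygons(x, y, annotations.by_role("exclude"))
    lab = np.where(in_t, "tumor", np.where(in_s, "stroma", ""))
    lab[in_x] = ""
    out = cells[lab != ""].copy()
    out["compartment_label"] = lab[lab != ""]
    for cls in ("tumor", "stroma"):
        if (out.compartment_label == cls).sum() == 0:
            raise ValueError(f"no training cells harvested for class {cls!r}")
    return out


def _make_classifier(family: str, seed: int):
    from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    if family == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed,
                                      n_jobs=1)
    if family == "extra_trees":
        return ExtraTreesClassifier(n_estimators=100, random_state=seed,
                                    n_jobs=1)
    if family == "logistic":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=2000,
                                                random_state=seed))
    raise ValueError(f"unknown classifier family {family!r}")


def fit_compartment_model(labeled: pd.DataFrame, seed: int = 0,
                          family: str = "random_forest",
                          min_per_class: int = 20) -> CompartmentModel:
    """Train the tumor/stroma classifier on harvested cells.

    Held-out accuracy is estimated on a stratified 25% split before the
    final model is refit on all labeled cells.  Deterministic given seed.
    """
    from sklearn.metrics import accuracy_score
    from sklearn.model_selection import train_test_split

    counts = labeled.compartment_label.value_counts()
    for cls in ("tumor", "stroma"):
        if counts.get(cls, 0) < min_per_class:
            raise ValueError(
                f"class starvation: {counts.get(cls, 0)} {cls!r} training "
                f"cells < required {min_per_class}")
    X = labeled[list(FEATURE_COLUMNS)].to_numpy()
    y = labeled.compartment_label.to_numpy()
    Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.25,
                                          random_state=seed, stratify=y)
    clf = _make_classifier(family, seed)
    clf.fit(Xtr, ytr)
    acc = float(accuracy_score(yte, clf.predict(Xte)))
    clf = _make_classifier(family, seed)
    clf.fit(X, y)
    return CompartmentModel(classifier=clf, feature_hash=feature_hash(),
                            n_train={c: int(counts.get(c, 0))
                                     for c in ("tumor", "stroma")},
                            heldout_accuracy=acc, family=family, seed=seed)


def assign_compartments(cells: pd.DataFrame, model: CompartmentModel,
                        annotations: AnnotationSet | None = None
                        ) -> pd.DataFrame:
    """Set the compartment column: excluded / tumor / stroma.

    Cells outside every inclusion polygon or inside any exclusion polygon
    are excluded; the rest are classified by the model.  With no
    annotations, the whole frame is included.
    """
    out = cells.copy()
    if len(out) == 0:
        out["compartment"] = pd.Series([], dtype=str)
        return out
    x = out.x.to_numpy()
    y = out.y.to_numpy()
    if annotations is not None and annotations.by_role("include"):
        inside = points_in_polygons(x, y, annotations.by_role("include"))
    else:
        inside = np.ones(len(out), bool)
    if annotations is not None:
        inside &= ~points_in_polygons(x, y, annotations.by_role("exclude"))
    comp = np.full(len(out), "excluded", dtype=object)
    if inside.any():
        comp[inside] = model.predict(out[inside])
    out["compartment"] = comp
    return out
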