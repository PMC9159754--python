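"""Cell-type and layer classification from measures and positional
information.

Classifiers operate on a FeatureTable (cells x named measures).  Supported
routes: value thresholding, 2D clustering (k-means or polygon gates — the
scripted equivalent of gating clusters on an interactive 2D measure plot),
a multi-class SVM for higher-dimensional separations, and radial/surface
layer detection for radially symmetric organs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AttributeMap

__all__ = [
    "FeatureTable",
    "threshold_classify",
    "cluster_2d",
    "SVMModel",
    "svm_train",
    "svm_predict",
    "detect_layers",
]


class FeatureTable:
    """Cells x features with an optional class-label column for training.

    Thin wrapper over a pandas DataFrame indexed by cell label; feature
    names must be unique, missing values are NaN.
    """

    def __init__(self, data: pd.DataFrame | dict, class_column: str = "class"):
        if isinstance(data, dict):
            data = pd.DataFrame(data)
        if data.index.has_duplicates:
            raise ValueError("duplicate cell labels in feature table")
        if data.columns.has_duplicates:
            raise ValueError("duplicate feature names")
        self.df = data
        self.class_column = class_column

    @classmethod
    def from_attribute_maps(cls, maps, class_map: AttributeMap | None = None):
        cols = {m.name: pd.Series(dict(m)) for m in maps}
        if class_map is not None:
            cols["class"] = pd.Series(dict(class_map))
        return cls(pd.DataFrame(cols))

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.df.columns if c != self.class_column]

    def features(self, names=None) -> pd.DataFrame:
        return self.df[list(names) if names else self.feature_names]

    def labels(self) -> np.ndarray:
        return self.df.index.to_numpy()


def threshold_classify(attr: AttributeMap, thresholds) -> AttributeMap:
    """Classes by half-open intervals: k sorted thresholds split values into
    k+1 classes (0-based); a value exactly at a threshold goes to the upper
    class."""
    thr = list(thresholds)
    if sorted(thr) != thr:
        raise ValueError("thresholds must be sorted ascending")
    out = AttributeMap(name=f"{attr.name}_class")
    for lab, v in attr.items():
        out[int(lab)] = int(np.searchsorted(thr, v, side="right"))
    return out


def cluster_2d(x: AttributeMap, y: AttributeMap, method: str = "kmeans",
               k: int = 2, seed: int = 0, gates=None) -> AttributeMap:
    """Two-feature cell classification.

    ``kmeans``: k-means on z-scored features (deterministic per seed).
    ``gates``: membership by point-in-polygon, gates evaluated in order
    (first match wins); ungated cells get class 0, gate ``i`` gives class
    ``i+1``.
    """
    labels = sorted(set(x) & set(y))
    pts = np.array([[x[l], y[l]] for l in labels], dtype=float)
    out = AttributeMap(name="cluster")
    if method == "kmeans":
        if k < 2:
            raise ValueError("k must be >= 2")
        from sklearn.cluster import KMeans
        mu = pts.mean(axis=0)
        sd = pts.std(axis=0)
        sd[sd == 0] = 1.0
        z = (pts - mu) / sd
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(z)
        for l, c in zip(labels, km.labels_):
            out[int(l)] = int(c)
    elif method == "gates":
        from shapely.geometry import Point, Polygon
        polys = [Polygon(np.asarray(g, dtype=float)) for g in (gates or [])]
        for l, p in zip(labels, pts):
            cls = 0
            for i, poly in enumerate(polys, start=1):
                if poly.covers(Point(p)):
                    cls = i
                    break
            out[int(l)] = cls
    else:
        raise ValueError("method must be 'kmeans' or 'gates'")
    return out


@dataclass
class SVMModel:
    """Trained multi-class SVM (RBF kernel, one-vs-one) with the feature
    standardization learned on the training set."""
    svc: object
    feature_names: list[str]
    mu: np.ndarray
    sd: np.ndarray


def svm_train(table: FeatureTable, C: float = 1.0, gamma: str | float = "auto",
              kernel: str = "rbf", seed: int = 0) -> SVMModel:
    """Train on the rows of ``table`` that carry a class label.  Features
    are z-scored with training-set statistics (stored in the model)."""
    from sklearn.svm import SVC
    df = table.df.dropna(subset=[table.class_column])
    if df[table.class_column].nunique() < 2:
        raise ValueError("need at least 2 classes to train")
    names = table.feature_names
    X = df[names].to_numpy(dtype=float)
    y = df[table.class_column].to_numpy()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    svc = SVC(C=C, gamma=gamma, kernel=kernel, random_state=seed)
    svc.fit((X - mu) / sd, y)
    return SVMModel(svc=svc, feature_names=names, mu=mu, sd=sd)


def svm_predict(model: SVMModel, table: FeatureTable) -> AttributeMap:
    """Predict classes for every row with complete features, using the
    model's stored standardization."""
    missing = [f for f in model.feature_names if f not in table.df.columns]
    if missing:
        raise ValueError(f"features absent from table: {missing}")
    df = table.df.dropna(subset=model.feature_names)
    X = df[model.feature_names].to_numpy(dtype=float)
    pred = model.svc.predict((X - model.mu) / model.sd)
    return AttributeMap({int(l): p for l, p in zip(df.index, pred)}, name="svm_class")


def detect_layers(values: AttributeMap, mode: str = "radial", k: int = 4,
                  thickness: float | None = None, seed: int = 0) -> AttributeMap:
    """Layer classification of a radially organised organ.

    ``radial``: 1D k-means on the relative radial coordinate; layers are
    numbered from the OUTSIDE in (layer 1 has the largest relative radius).
    ``surface``: layer = floor(distance / thickness) + 1 on absolute
    surface distances (layer 1 nearest the surface).
    """
    out = AttributeMap(name="layer")
    labs = sorted(values)
    v = np.array([values[l] for l in labs], dtype=float)
    if mode == "surface":
        if thickness is None or thickness <= 0:
            raise ValueError("surface mode needs a positive layer thickness")
        for l, val in zip(labs, v):
            out[int(l)] = int(np.floor(val / thickness)) + 1
        return out
    if mode != "radial":
        raise ValueError("mode must be 'radial' or 'surface'")
    if k > len(np.unique(v)):
        raise ValueError("k exceeds the number of distinct values")
    if k == 1:
        for l in labs:
            out[int(l)] = 1
        return out
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(v[:, None])
    # order clusters by mean relative radius, outermost first
    order = np.argsort(-km.cluster_centers_.ravel())
    rank = {int(c): i + 1 for i, c in enumerate(order)}
    for l, c in zip(labs, km.labels_):
        out[int(l)] = rank[int(c)]
    return out
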