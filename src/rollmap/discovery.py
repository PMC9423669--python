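"""Unsupervised discovery of involved / uninvolved patch classes.

Patch embeddings from the final involvement classifier are reduced with
PCA to the smallest number of components capturing a target fraction of
variance (default 95%), then clustered with k-means (defaults: 4 involved
classes, 3 uninvolved classes).  Per-mouse class proportions — the
Uninvolved share plus one share per discovered Involved class, summing to
1 over kept patches — are the downstream phenotype features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

K_INVOLVED = 4
K_UNINVOLVED = 3


class VarianceTargetPCA(TransformerMixin, BaseEstimator):
    """PCA retaining the minimal component count reaching a variance target.

    Sign convention: each component's largest-magnitude entry is positive,
    making the transform deterministic across SVD implementations.
    """

    def __init__(self, target_variance: float = 0.95):
        self.target_variance = target_variance

    def fit(self, X, y=None):
        if not 0.0 < self.target_variance <= 1.0:
            raise ValueError("target_variance must lie in (0, 1]")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or len(X) < 2:
            raise ValueError("need a 2-D array with >= 2 samples")
        pca = PCA(svd_solver="full").fit(X)
        ratios = pca.explained_variance_ratio_
        cum = np.cumsum(ratios)
        n = int(np.argmax(cum >= self.target_variance - 1e-12)) + 1
        comps = pca.components_[:n].copy()
        flip = comps[np.arange(n), np.abs(comps).argmax(axis=1)] < 0
        comps[flip] *= -1
        self.mean_ = pca.mean_
        self.components_ = comps
        self.explained_variance_ratio_ = ratios[:n]
        self.all_variance_ratio_ = ratios
        self.n_components_ = n
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.mean_.size:
            raise ValueError("feature width mismatch")
        return (X - self.mean_) @ self.components_.T


def fit_pca(features, target_variance: float = 0.95) -> VarianceTargetPCA:
    return VarianceTargetPCA(target_variance=target_variance).fit(features)


class PatchKMeans(BaseEstimator):
    """K-means patch-class model in reduced feature space.

    ``class_names`` attaches human-readable names to the anonymous
    clusters (the field's names come from expert inspection); defaults to
    ``class_1 .. class_k``.
    """

    def __init__(self, k: int, random_state: int = 0, restarts: int = 10,
                 class_names: tuple[str, ...] | None = None):
        self.k = k
        self.random_state = random_state
        self.restarts = restarts
        self.class_names = class_names

    def fit(self, Z, y=None):
        Z = np.asarray(Z, dtype=np.float64)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(Z) < self.k:
            raise ValueError(f"k={self.k} exceeds {len(Z)} points")
        names = self.class_names or tuple(f"class_{i+1}" for i in range(self.k))
        if len(names) != self.k:
            raise ValueError("number of class names must equal k")
        km = KMeans(n_clusters=self.k, n_init=self.restarts,
                    random_state=self.random_state)
        km.fit(Z)
        self.kmeans_ = km
        self.cluster_centers_ = km.cluster_centers_
        self.names_ = tuple(names)
        self.labels_ = km.labels_
        return self

    def predict(self, Z) -> np.ndarray:
        check_is_fitted(self, "kmeans_")
        Z = np.asarray(Z, dtype=np.float64)
        # nearest centroid; ties resolve to the lowest centroid index
        d = np.linalg.norm(Z[:, None, :] - self.cluster_centers_[None], axis=2)
        return d.argmin(axis=1)

    def predict_names(self, Z) -> np.ndarray:
        return np.asarray(self.names_)[self.predict(Z)]


def fit_kmeans(Z, k: int, seed: int = 0, restarts: int = 10,
               class_names: tuple[str, ...] | None = None) -> PatchKMeans:
    return PatchKMeans(k=k, random_state=seed, restarts=restarts,
                       class_names=class_names).fit(Z)


def representatives(model: PatchKMeans, Z, refs, n: int = 8) -> dict[str, list]:
    """Per class, the n assigned patches nearest the centroid (ascending
    distance, ties in manifest order)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    Z = np.asarray(Z, dtype=np.float64)
    assign = model.predict(Z)
    out: dict[str, list] = {}
    refs = list(refs)
    for ci, name in enumerate(model.names_):
        idx = np.nonzero(assign == ci)[0]
        if idx.size == 0:
            import warnings
            warnings.warn(f"class {name!r} has no assigned patches")
            out[name] = []
            continue
        d = np.linalg.norm(Z[idx] - model.cluster_centers_[ci], axis=1)
        order = idx[np.argsort(d, kind="stable")][:n]
        out[name] = [refs[i] for i in order]
    return out


def class_proportions(calls: pd.DataFrame, class_names: tuple[str, ...],
                      mice=None) -> pd.DataFrame:
    """Per-mouse proportion features from per-patch class calls.

    ``calls`` needs columns ``mouse_id`` and ``call``, where ``call`` is
    either ``Uninvolved`` or one of ``class_names``; the denominator is the
    mouse's kept-patch count.  ``mice`` optionally fixes the expected row
    index (a mouse with zero kept patches is then rejected by name).
    Returns one row per mouse with columns ``Uninvolved`` + class names,
    each row summing to 1.
    """
    order = ("Uninvolved",) + tuple(class_names)
    unknown = set(calls["call"]) - set(order)
    if unknown:
        raise ValueError(f"unknown calls: {sorted(unknown)}")
    counts = (calls.groupby(["mouse_id", "call"]).size()
              .unstack(fill_value=0).reindex(columns=order, fill_value=0))
    if mice is not None:
        counts = counts.reindex(index=list(mice), fill_value=0)
    if (counts.sum(axis=1) == 0).any():
        empty = counts.index[counts.sum(axis=1) == 0].tolist()
        raise ValueError(f"mice with zero kept patches: {empty}")
    return counts.div(counts.sum(axis=1), axis=0)


def save_class_model(pca: VarianceTargetPCA, km: PatchKMeans,
                     path: str | Path) -> None:
    """Serialize transform + centroids as JSON (text-only artifact)."""
    obj = {
        "target_variance": pca.target_variance,
        "mean": pca.mean_.tolist(),
        "components": pca.components_.tolist(),
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
        "k": km.k,
        "centroids": km.cluster_centers_.tolist(),
        "names": list(km.names_),
    }
    Path(path).write_text(json.dumps(obj))


def load_class_model(path: str | Path) -> tuple[VarianceTargetPCA, PatchKMeans]:
    obj = json.loads(Path(path).read_text())
    pca = VarianceTargetPCA(target_variance=obj["target_variance"])
    pca.mean_ = np.asarray(obj["mean"])
    pca.components_ = np.asarray(obj["components"])
    pca.explained_variance_ratio_ = np.asarray(obj["explained_variance_ratio"])
    pca.n_components_ = len(pca.components_)
    km = PatchKMeans(k=obj["k"], class_names=tuple(obj["names"]))
    km.cluster_centers_ = np.asarray(obj["centroids"])
    km.names_ = tuple(obj["names"])
    from sklearn.cluster import KMeans as _KM
    inner = _KM(n_clusters=km.k, n_init=1)
    inner.cluster_centers_ = km.cluster_centers_
    inner._n_threads = 1
    km.kmeans_ = inner
    return pca, km
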