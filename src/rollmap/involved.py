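"""Two-phase involved-vs-uninvolved patch classifier training.

Phase 1 trains on slide-level labels: every patch from a colitis-model
mouse is labelled ``Colitis``, every patch from a control mouse
``Control``.  Because colitis colons retain healthy mucosa, a large share
of those ``Colitis`` labels are wrong at the patch level.  Phase 1's hidden
layer is then used as a feature extractor; k-means over the embeddings
groups patches into texture classes, and each cluster is relabelled
``Involved`` or ``Uninvolved`` by an enrichment rule on per-mouse cluster
proportions: a cluster is Involved iff it is (practically) absent from
control mice and more common in colitis mice.  Phase 2 retrains the same
architecture on the refined patch-level labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import confusion_matrix, f1_score

from .classifier import SmallImageClassifier

COLITIS, CONTROL = "Colitis", "Control"
INVOLVED_LABEL, UNINVOLVED_LABEL = "Involved", "Uninvolved"


@dataclass(frozen=True)
class CohortSplit:
    """Mouse-level train/validation/test partition."""

    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.validation), set(self.test)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split sets must be pairwise disjoint")
        if not (self.train and self.test):
            raise ValueError("train and test splits must be non-empty")


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    ideal = np.asarray(fractions) * n
    counts = np.floor(ideal).astype(int)
    rem = ideal - counts
    for i in np.argsort(-rem, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def split_cohort(mouse_ids, model_labels=None,
                 fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
                 seed: int = 0) -> CohortSplit:
    """Split mice into train/validation/test at the mouse level.

    Stratified by model label where group sizes allow; sizes follow
    largest-remainder rounding of ``fractions``; deterministic per seed.
    """
    mouse_ids = list(mouse_ids)
    if len(mouse_ids) < 3:
        raise ValueError(f"need >= 3 mice to split, got {len(mouse_ids)}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    labels = list(model_labels) if model_labels is not None else ["_"] * len(mouse_ids)
    rng = np.random.default_rng(seed)
    buckets: list[list[str]] = [[], [], []]
    for lab in sorted(set(labels)):
        group = [m for m, l in zip(mouse_ids, labels) if l == lab]
        order = rng.permutation(len(group))
        group = [group[i] for i in order]
        counts = _largest_remainder(len(group), tuple(fractions))
        i = 0
        for b, c in enumerate(counts):
            buckets[b].extend(group[i:i + c])
            i += c
    # guarantee a non-empty test set (validation may be empty for tiny cohorts)
    if not buckets[2]:
        buckets[2].append(buckets[0].pop())
    return CohortSplit(tuple(buckets[0]), tuple(buckets[1]), tuple(buckets[2]))


class InvolvedPatchClassifier(SmallImageClassifier):
    """Binary involvement classifier; defaults sized for 512-wide embeddings."""

    def __init__(self, input_size: int = 16, feature_width: int = 512,
                 epochs: int = 30, learning_rate: float = 1e-3,
                 batch_size: int = 64, random_state: int = 0):
        super().__init__(input_size=input_size, feature_width=feature_width,
                         epochs=epochs, learning_rate=learning_rate,
                         batch_size=batch_size, random_state=random_state)


def train_patch_classifier(patches, labels, config: dict | None = None,
                           seed: int = 0, val_patches=None, val_labels=None
                           ) -> InvolvedPatchClassifier:
    """Train the binary patch classifier; best-validation-F1 checkpoint wins."""
    model = InvolvedPatchClassifier(random_state=seed, **(config or {}))
    model.fit(patches, labels, X_val=val_patches, y_val=val_labels)
    return model


def extract_features(model: SmallImageClassifier, patches) -> np.ndarray:
    """Per-patch embeddings (order preserving, deterministic)."""
    return model.transform(patches)


class ClusterRelabeler(BaseEstimator):
    """Pseudo-label refinement via k-means over patch embeddings.

    For each cluster c, let p_ctrl(c) be the mean per-mouse proportion of a
    control mouse's patches falling in c, and p_col(c) the same over colitis
    mice.  c is ``Involved`` iff p_col > p_ctrl and p_ctrl < ``control_tau``
    (i.e. the texture is essentially absent from healthy colons and enriched
    in colitis ones); otherwise ``Uninvolved``.  Refined labels: patches
    from control mice are always ``Uninvolved``; patches from colitis mice
    inherit their cluster's label.  ``overrides`` maps cluster index to a
    forced label (the manual-override hook).
    """

    def __init__(self, k: int = 5, control_tau: float = 0.05,
                 restarts: int = 10, random_state: int = 0,
                 overrides: dict | None = None):
        self.k = k
        self.control_tau = control_tau
        self.restarts = restarts
        self.random_state = random_state
        self.overrides = overrides

    def fit(self, features, mouse_ids, slide_status):
        """``slide_status``: per-patch Colitis/Control slide-level label."""
        features = np.asarray(features)
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if len(features) < self.k:
            raise ValueError(f"k={self.k} exceeds {len(features)} patches")
        status = np.asarray(slide_status)
        mouse_ids = np.asarray(mouse_ids)
        present = set(status)
        if not {COLITIS, CONTROL} <= present:
            raise ValueError("need both control and colitis slides represented")
        km = KMeans(n_clusters=self.k, n_init=self.restarts,
                    random_state=self.random_state)
        assign = km.fit_predict(features)

        per_mouse = pd.DataFrame({"mouse": mouse_ids, "cluster": assign,
                                  "status": status})
        prop = (per_mouse.groupby(["mouse", "cluster"]).size()
                .unstack(fill_value=0)
                .reindex(columns=range(self.k), fill_value=0))
        prop = prop.div(prop.sum(axis=1), axis=0)
        mouse_status = per_mouse.drop_duplicates("mouse").set_index("mouse")["status"]
        p_ctrl = prop.loc[mouse_status == CONTROL].mean(axis=0)
        p_col = prop.loc[mouse_status == COLITIS].mean(axis=0)

        labels = {}
        for c in range(self.k):
            involved = (p_col[c] > p_ctrl[c]) and (p_ctrl[c] < self.control_tau)
            labels[c] = INVOLVED_LABEL if involved else UNINVOLVED_LABEL
        for c, lab in (self.overrides or {}).items():
            if lab not in (INVOLVED_LABEL, UNINVOLVED_LABEL):
                raise ValueError(f"invalid override label {lab!r}")
            labels[int(c)] = lab

        refined = np.where(status == CONTROL, UNINVOLVED_LABEL,
                           [labels[a] for a in assign])
        self.kmeans_ = km
        self.assignments_ = assign
        self.mouse_ids_ = mouse_ids
        self.status_ = status
        self.cluster_labels_ = labels
        self.enrichment_ = pd.DataFrame({"p_ctrl": p_ctrl, "p_col": p_col,
                                         "label": pd.Series(labels)})
        self.refined_labels_ = refined
        return self

    def fit_relabel(self, features, mouse_ids, slide_status) -> np.ndarray:
        return self.fit(features, mouse_ids, slide_status).refined_labels_


def cluster_and_relabel(features, mouse_ids, slide_status, k: int = 5,
                        control_tau: float = 0.05, seed: int = 0,
                        overrides: dict | None = None) -> ClusterRelabeler:
    return ClusterRelabeler(k=k, control_tau=control_tau, random_state=seed,
                            overrides=overrides).fit(features, mouse_ids,
                                                     slide_status)


def evaluate_patch_model(model, patches, truth_labels) -> dict:
    """Confusion matrix (rows = truth), per-class F1 and weighted overall F1."""
    truth = np.asarray(truth_labels)
    if truth.size == 0:
        raise ValueError("test set must be non-empty")
    unknown = set(truth) - set(model.classes_)
    if unknown:
        raise ValueError(f"unknown truth labels: {sorted(unknown)}")
    pred = model.predict(patches)
    labels = list(model.classes_)
    cm = confusion_matrix(truth, pred, labels=labels)
    per_class = f1_score(truth, pred, labels=labels, average=None,
                         zero_division=0)
    overall = f1_score(truth, pred, labels=labels, average="weighted",
                       zero_division=0)
    return {
        "labels": labels,
        "confusion": cm,
        "per_class_f1": dict(zip(labels, per_class.tolist())),
        "overall_f1": float(overall),
    }
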