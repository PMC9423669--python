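"""Tissue classification, tissue maps and the 65% patch-filter rule.

A small 4-class classifier ({Background, Muscle, Tissue, Submucosa}) is
trained on 32x32 patches and applied block-wise to whole slides to produce
a tissue map.  Patches whose area is more than 65% Background/Muscle on the
map are filtered out before involvement classification; Tissue and
Submucosa are both "wanted".  A fraction of exactly 0.65 is kept — only
strictly more than the threshold is removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from sklearn.model_selection import train_test_split

from .classifier import SmallImageClassifier
from .patching import PatchRef

TISSUE_CLASSES = ("Background", "Muscle", "Tissue", "Submucosa")
UNWANTED = ("Background", "Muscle")
BLOCK_SIZE = 32
FILTER_THRESHOLD = 0.65


@dataclass
class TissueMap:
    """Per-block tissue classes over a slide.

    ``grid`` holds indices into :data:`TISSUE_CLASSES`, one cell per
    non-overlapping ``block_size`` block, row-major.  ``padded`` flags cells
    classified on zero-padded partial border blocks.
    """

    grid: np.ndarray
    slide_dims: tuple[int, int]
    block_size: int = BLOCK_SIZE
    padded: np.ndarray | None = None

    def __post_init__(self) -> None:
        h, w = self.slide_dims
        exp = (int(np.ceil(h / self.block_size)), int(np.ceil(w / self.block_size)))
        if self.grid.shape != exp:
            raise ValueError(f"grid shape {self.grid.shape} != expected {exp}")

    def unwanted(self) -> np.ndarray:
        """Boolean grid: True where the cell is Background or Muscle."""
        ids = [TISSUE_CLASSES.index(c) for c in UNWANTED]
        return np.isin(self.grid, ids)

    def pixel_mask(self) -> np.ndarray:
        """Per-pixel boolean mask of wanted (Tissue/Submucosa) area."""
        up = np.kron(~self.unwanted(), np.ones((self.block_size, self.block_size), bool))
        h, w = self.slide_dims
        return up[:h, :w]


class TissuePatchClassifier(SmallImageClassifier):
    """4-class tissue classifier over 32x32 RGB blocks."""

    def __init__(self, input_size: int = 8, feature_width: int = 96,
                 epochs: int = 40, learning_rate: float = 1e-3,
                 batch_size: int = 64, random_state: int = 0):
        super().__init__(input_size=input_size, feature_width=feature_width,
                         epochs=epochs, learning_rate=learning_rate,
                         batch_size=batch_size, random_state=random_state)

    def fit(self, X, y, X_val=None, y_val=None):
        y = np.asarray(y)
        present = set(np.unique(y))
        missing = [c for c in TISSUE_CLASSES if c not in present]
        if missing:
            raise ValueError(f"training data missing tissue classes: {missing}")
        return super().fit(X, y, X_val, y_val)


def train_tissue_model(patches: np.ndarray, labels, config: dict | None = None,
                       seed: int = 0) -> TissuePatchClassifier:
    """Train the tissue classifier and report held-out weighted F1.

    ``patches``: (n, 32, 32, 3) uint8; ``labels``: tissue class names with
    >= 10 patches per class.  A stratified 80/20 split provides the held-out
    F1 stored on ``model.holdout_f1_``.
    """
    labels = np.asarray(labels)
    present, counts = np.unique(labels, return_counts=True)
    missing = [c for c in TISSUE_CLASSES if c not in set(present)]
    if missing:
        raise ValueError(f"training data missing tissue classes: {missing}")
    if counts.min() < 10:
        raise ValueError("need >= 10 patches per tissue class")
    model = TissuePatchClassifier(random_state=seed, **(config or {}))
    X_tr, X_te, y_tr, y_te = train_test_split(
        np.asarray(patches), labels, test_size=0.2, stratify=labels,
        random_state=seed)
    model.fit(X_tr, y_tr, X_val=X_te, y_val=y_te)
    from sklearn.metrics import f1_score
    model.holdout_f1_ = float(f1_score(y_te, model.predict(X_te), average="weighted"))
    return model


def build_tissue_map(model: TissuePatchClassifier, slide: np.ndarray,
                     block_size: int = BLOCK_SIZE) -> TissueMap:
    """Classify each non-overlapping block of ``slide``; partial border
    blocks are zero-padded and flagged."""
    h, w = slide.shape[:2]
    if min(h, w) < block_size:
        raise ValueError("slide smaller than one block")
    gh, gw = int(np.ceil(h / block_size)), int(np.ceil(w / block_size))
    ph, pw = gh * block_size, gw * block_size
    padded_img = np.zeros((ph, pw, 3), dtype=slide.dtype)
    padded_img[:h, :w] = slide
    blocks = (padded_img
              .reshape(gh, block_size, gw, block_size, 3)
              .transpose(0, 2, 1, 3, 4)
              .reshape(gh * gw, block_size, block_size, 3))
    pred = model.predict(blocks)
    grid = np.array([TISSUE_CLASSES.index(p) for p in pred],
                    dtype=np.uint8).reshape(gh, gw)
    padded = np.zeros((gh, gw), dtype=bool)
    if ph > h:
        padded[-1, :] = True
    if pw > w:
        padded[:, -1] = True
    return TissueMap(grid=grid, slide_dims=(h, w), block_size=block_size,
                     padded=padded)


def unwanted_fraction(ref: PatchRef, tmap: TissueMap) -> float:
    """Fraction of the patch area covered by Background/Muscle map cells,
    weighting partially covered cells by overlap area."""
    h, w = tmap.slide_dims
    if not ref.in_bounds(h, w):
        raise ValueError(f"patch {ref} out of slide bounds {(h, w)}")
    b = tmap.block_size
    unwanted = tmap.unwanted()
    j0, j1 = ref.x // b, (ref.x + ref.size - 1) // b
    i0, i1 = ref.y // b, (ref.y + ref.size - 1) // b
    cols = np.arange(j0, j1 + 1)
    rows = np.arange(i0, i1 + 1)
    ox = (np.minimum((cols + 1) * b, ref.x + ref.size)
          - np.maximum(cols * b, ref.x)).clip(min=0)
    oy = (np.minimum((rows + 1) * b, ref.y + ref.size)
          - np.maximum(rows * b, ref.y)).clip(min=0)
    area = np.outer(oy, ox)
    bad = unwanted[i0:i1 + 1, j0:j1 + 1]
    return float((area * bad).sum() / (ref.size * ref.size))


def filter_patches(refs: list[PatchRef], tmap: TissueMap,
                   threshold: float = FILTER_THRESHOLD) -> list[PatchRef]:
    """Keep refs whose unwanted fraction is <= threshold (order preserved)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [r for r in refs if unwanted_fraction(r, tmap) <= threshold]


def write_tissue_map(tmap: TissueMap, path: str | Path) -> None:
    """Serialize as a class-id PNG plus a JSON sidecar."""
    path = Path(path)
    iio.imwrite(path, tmap.grid.astype(np.uint8))
    sidecar = {
        "block_size": tmap.block_size,
        "slide_dims": list(tmap.slide_dims),
        "class_order": list(TISSUE_CLASSES),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_tissue_map(path: str | Path) -> TissueMap:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return TissueMap(grid=iio.imread(path),
                     slide_dims=tuple(meta["slide_dims"]),
                     block_size=meta["block_size"])
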