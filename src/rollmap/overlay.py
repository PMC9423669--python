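"""Per-pixel confidence averaging and involvement overlays.

Every (possibly overlapping) patch contributes its Involved confidence to
all pixels in its window; the per-pixel mean over contributing patches is
the Involved confidence field (the Uninvolved field is its complement).
Pixels with mean strictly above 0.5 are painted red, other covered pixels
green; Background/Muscle map regions and uncovered pixels are excluded
from the prediction-pixel counts and left unpainted.  The
``InvolvedProportion`` of a slide is involved / (involved + uninvolved)
prediction pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .patching import PatchRef
from .tissue import TissueMap

RED = np.array([220, 40, 40], dtype=np.float64)
GREEN = np.array([40, 180, 60], dtype=np.float64)


@dataclass
class ConfidenceField:
    """Accumulated Involved confidences over a slide."""

    total: np.ndarray   # per-pixel summed Involved confidence
    count: np.ndarray   # per-pixel number of contributing patches

    @property
    def covered(self) -> np.ndarray:
        return self.count > 0

    def mean(self) -> np.ndarray:
        """Mean Involved confidence; NaN where uncovered."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.count > 0, self.total / self.count, np.nan)

    def uninvolved_mean(self) -> np.ndarray:
        return 1.0 - self.mean()


@dataclass
class OverlayResult:
    overlay: np.ndarray
    involved_pixels: int
    uninvolved_pixels: int
    masked_pixels: int

    @property
    def involved_proportion(self) -> float:
        return involved_proportion(self)


def accumulate(predictions: Iterable[tuple[PatchRef, float]],
               dims: tuple[int, int]) -> ConfidenceField:
    """Sum patch confidences into per-pixel total and coverage count."""
    h, w = dims
    total = np.zeros((h, w), dtype=np.float64)
    count = np.zeros((h, w), dtype=np.int64)
    for ref, conf in predictions:
        if not ref.in_bounds(h, w):
            raise ValueError(f"patch {ref} out of slide bounds {(h, w)}")
        sl = (slice(ref.y, ref.y + ref.size), slice(ref.x, ref.x + ref.size))
        total[sl] += conf
        count[sl] += 1
    return ConfidenceField(total=total, count=count)


def render_overlay(field: ConfidenceField, tmap: TissueMap, base: np.ndarray,
                   threshold: float = 0.5, alpha: float = 0.35) -> OverlayResult:
    """Tint the base image by predicted involvement and count prediction pixels.

    A pixel is a prediction pixel iff it is covered by at least one patch
    and its tissue-map block is Tissue or Submucosa.  Involved requires
    mean strictly greater than ``threshold`` (a 50% tie is Uninvolved).
    """
    h, w = field.total.shape
    if tmap.slide_dims != (h, w) or base.shape[:2] != (h, w):
        raise ValueError("field, tissue map and base image dims must match")
    wanted = tmap.pixel_mask()
    covered = field.covered
    predict = covered & wanted
    mean = field.mean()
    involved = predict & (mean > threshold)
    uninvolved = predict & ~(mean > threshold)

    overlay = base.astype(np.float64).copy()
    overlay[involved] = (1 - alpha) * overlay[involved] + alpha * RED
    overlay[uninvolved] = (1 - alpha) * overlay[uninvolved] + alpha * GREEN
    return OverlayResult(
        overlay=np.clip(np.rint(overlay), 0, 255).astype(np.uint8),
        involved_pixels=int(involved.sum()),
        uninvolved_pixels=int(uninvolved.sum()),
        masked_pixels=int(h * w - predict.sum()),
    )


def involved_proportion(result: OverlayResult) -> float:
    """Involved share of all prediction pixels in the overlay."""
    denom = result.involved_pixels + result.uninvolved_pixels
    if denom == 0:
        raise ValueError("no prediction pixels: slide fully masked or uncovered")
    return result.involved_pixels / denom
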