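"""Procedural texture classes standing in for H&E histology.

Ten texture classes cover the synthetic swiss-roll vocabulary: three
uninvolved mucosal appearances (``Crypts``, ``LightlyPacked``, ``Rosettes``),
four involved/diseased appearances (``Inflammatory``, ``CryptDropout``,
``CryptDilation``, ``DistortedGlands``) and three non-mucosal classes
(``Background``, ``Muscle``, ``Submucosa``).  Each texture is a base colour
plus a jittered grid of ring/blob/stipple elements; classes are pairwise
distinct in mean colour so that patch classifiers can learn them, which is
all the downstream pipeline needs — no attempt at photorealism is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk

UNINVOLVED = "Uninvolved"
INVOLVED = "Involved"
NON_MUCOSA = "NonMucosa"


@dataclass(frozen=True)
class TextureClass:
    """A procedural texture: base colour plus element geometry.

    ``density`` is the expected element count per 10^4 px^2; ``jitter`` is the
    element-position jitter as a fraction of the grid spacing.
    """

    name: str
    involvement: str
    base_color: tuple[int, int, int]
    element_color: tuple[int, int, int] = (0, 0, 0)
    element_radius: int = 0
    density: float = 0.0
    jitter: float = 0.4
    style: str = "ring"  # ring | blob | stipple
    noise_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.involvement not in (UNINVOLVED, INVOLVED, NON_MUCOSA):
            raise ValueError(f"unknown involvement {self.involvement!r}")


# Class-id order is frozen: truth masks store indices into this list.
CLASS_ORDER: tuple[str, ...] = (
    "Background",
    "Muscle",
    "Submucosa",
    "Crypts",
    "LightlyPacked",
    "Rosettes",
    "Inflammatory",
    "CryptDropout",
    "CryptDilation",
    "DistortedGlands",
)

TEXTURES: dict[str, TextureClass] = {
    t.name: t
    for t in [
        # Background is blank glass: near-white, no elements, tight noise.
        TextureClass("Background", NON_MUCOSA, (250, 250, 250), noise_sd=2.0),
        TextureClass("Muscle", NON_MUCOSA, (214, 140, 158), (186, 106, 128),
                     element_radius=3, density=5.0, style="stipple"),
        # pale orange-pink loose connective tissue, distinct from the
        # pink/purple mucosal palette
        TextureClass("Submucosa", NON_MUCOSA, (244, 214, 182), (226, 188, 148),
                     element_radius=3, density=2.0, style="blob"),
        TextureClass("Crypts", UNINVOLVED, (206, 151, 190), (122, 62, 140),
                     element_radius=5, density=4.0, style="ring"),
        TextureClass("LightlyPacked", UNINVOLVED, (231, 198, 219), (150, 95, 160),
                     element_radius=6, density=1.5, style="ring"),
        TextureClass("Rosettes", UNINVOLVED, (212, 174, 162), (140, 80, 120),
                     element_radius=8, density=2.0, style="ring"),
        # involved textures: markedly basophilic (inflammation), eosinophilic
        # pale (dropout), lumen-pale blue (dilation) or dark mauve (distortion)
        TextureClass("Inflammatory", INVOLVED, (140, 95, 180), (80, 35, 130),
                     element_radius=2, density=12.0, style="stipple"),
        TextureClass("CryptDropout", INVOLVED, (238, 148, 130), (205, 110, 95),
                     element_radius=4, density=1.0, style="blob"),
        TextureClass("CryptDilation", INVOLVED, (170, 170, 230), (110, 105, 180),
                     element_radius=10, density=1.2, style="ring"),
        TextureClass("DistortedGlands", INVOLVED, (165, 120, 135), (100, 60, 90),
                     element_radius=7, density=3.0, style="ring"),
    ]
}

UNINVOLVED_CLASSES: tuple[str, ...] = tuple(
    n for n in CLASS_ORDER if TEXTURES[n].involvement == UNINVOLVED
)
INVOLVED_CLASSES: tuple[str, ...] = tuple(
    n for n in CLASS_ORDER if TEXTURES[n].involvement == INVOLVED
)
NON_MUCOSA_CLASSES: tuple[str, ...] = tuple(
    n for n in CLASS_ORDER if TEXTURES[n].involvement == NON_MUCOSA
)
MUCOSAL_CLASSES: tuple[str, ...] = UNINVOLVED_CLASSES + INVOLVED_CLASSES

# Deviation of a rendered texture's channel mean from its base colour is
# bounded by element coverage; 20 grey levels is the contract.
MEAN_COLOR_TOL = 20.0


def class_id(name: str) -> int:
    """Index of ``name`` in the frozen class order."""
    try:
        return CLASS_ORDER.index(name)
    except ValueError:
        raise KeyError(f"unknown texture class {name!r}") from None


def render_texture(cls: TextureClass | str, shape: tuple[int, int],
                   seed: int) -> np.ndarray:
    """Render a texture of ``shape`` (H, W); deterministic in (cls, shape, seed)."""
    if isinstance(cls, str):
        if cls not in TEXTURES:
            raise KeyError(f"unknown texture class {cls!r}")
        cls = TEXTURES[cls]
    h, w = shape
    rng = np.random.default_rng([seed, class_id(cls.name)])
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = cls.base_color
    img += rng.normal(0.0, cls.noise_sd, size=(h, w, 3))
    if cls.density > 0 and cls.element_radius > 0:
        # jittered grid of elements at the requested density
        spacing = max(2.0, np.sqrt(1e4 / cls.density))
        ys = np.arange(spacing / 2, h, spacing)
        xs = np.arange(spacing / 2, w, spacing)
        gy, gx = np.meshgrid(ys, xs, indexing="ij")
        jit = rng.normal(0.0, cls.jitter * spacing, size=(2,) + gy.shape)
        cy = gy.ravel() + jit[0].ravel()
        cx = gx.ravel() + jit[1].ravel()
        r = cls.element_radius
        for yy, xx in zip(cy, cx):
            rr, cc = disk((yy, xx), r, shape=(h, w))
            img[rr, cc] = cls.element_color
            if cls.style == "ring" and r > 2:
                rr, cc = disk((yy, xx), r - 2, shape=(h, w))
                img[rr, cc] = cls.base_color
    if cls.name == "Background":
        # blank glass: keep all channels near-white
        img = np.clip(img, 241, 255)
    return np.clip(img, 0, 255).astype(np.uint8)


def render_texture_patch(cls: TextureClass | str, size: int, seed: int) -> np.ndarray:
    """Square texture patch of side ``size`` pixels (size >= 16)."""
    if size < 16:
        raise ValueError(f"patch size must be >= 16, got {size}")
    return render_texture(cls, (size, size), seed)
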