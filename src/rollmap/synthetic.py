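"""Synthetic swiss-roll cohort generator.

A swiss roll is a whole mouse colon coiled flat on one slide; the spiral
centre is the proximal end.  Each synthetic slide is an Archimedean spiral
band on a near-white background.  The band is split radially into a mucosal
band, a submucosal stripe and a muscle stripe; the mucosa is painted with
uninvolved textures and, for colitis-model profiles, contiguous arcs of
involved textures whose position along the spiral follows the model's
injury pattern (DSS-like injury spares the proximal half; the inducible
Klf5-knockout-like pattern involves it; "uniform" places arcs anywhere).

Clinical score is coupled to the realized involved-area fraction through a
linear model with Gaussian noise, ``score = round(clip(12*f + eps, 0, 12))``,
so that cohorts reproduce the moderate involvement-score correlation seen
in real colitis cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import imageio.v3 as iio

from .textures import (
    CLASS_ORDER,
    INVOLVED_CLASSES,
    UNINVOLVED_CLASSES,
    class_id,
    render_texture,
)

MODEL_NAMES = ("Control", "KLF5", "DSS", "Combined")
INJURY_PATTERNS = ("none", "proximal_sparing", "proximal_involving", "uniform")


@dataclass(frozen=True)
class ModelProfile:
    """Injury phenotype of one mouse model.

    ``involved_class_mix`` orders probabilities as
    (Inflammatory, CryptDropout, CryptDilation, DistortedGlands);
    ``uninvolved_class_mix`` as (Crypts, LightlyPacked, Rosettes).
    Colitis models skew their healthy mucosa toward the LightlyPacked
    appearance (peri-injury mucosa), controls are uniform.
    """

    model_name: str
    involved_fraction_mean: float
    injury_pattern: str
    involved_class_mix: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    uninvolved_class_mix: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    involved_fraction_sd: float = 0.06

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model_name!r}")
        if self.injury_pattern not in INJURY_PATTERNS:
            raise ValueError(f"unknown injury pattern {self.injury_pattern!r}")
        if not 0.0 <= self.involved_fraction_mean <= 1.0:
            raise ValueError("involved_fraction_mean must lie in [0, 1]")
        if self.model_name == "Control" and self.involved_fraction_mean > 0:
            raise ValueError("Control profile must have involved_fraction_mean = 0")
        for mix, k in ((self.involved_class_mix, 4), (self.uninvolved_class_mix, 3)):
            arr = np.asarray(mix, dtype=float)
            if arr.size != k or (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"class mix must be {k} non-negative values summing to 1")

    @property
    def is_control(self) -> bool:
        return self.model_name == "Control"


#: Default per-model profiles.  Involved-area fractions are generator
#: configuration, not literature claims; class mixes are chosen so the four
#: models differ in composition (DSS-like injury is inflammation/dropout
#: dominated, the Klf5-knockout-like model is architecture-distortion
#: dominated, the combined model mixes both).
DEFAULT_PROFILES: dict[str, ModelProfile] = {
    "Control": ModelProfile("Control", 0.0, "none"),
    "KLF5": ModelProfile(
        "KLF5", 0.5, "proximal_involving",
        involved_class_mix=(0.05, 0.10, 0.40, 0.45),
        uninvolved_class_mix=(0.10, 0.80, 0.10),
    ),
    "DSS": ModelProfile(
        "DSS", 0.45, "proximal_sparing",
        involved_class_mix=(0.45, 0.35, 0.10, 0.10),
        uninvolved_class_mix=(0.10, 0.80, 0.10),
    ),
    "Combined": ModelProfile(
        "Combined", 0.6, "uniform",
        involved_class_mix=(0.25, 0.25, 0.25, 0.25),
        uninvolved_class_mix=(0.10, 0.80, 0.10),
    ),
}


@dataclass(frozen=True)
class SpiralGeometry:
    """Archimedean spiral layout of a synthetic swiss roll."""

    size: int = 1024            # square raster side, px
    turns: float = 4.5          # number of spiral turns
    band_frac: float = 0.62     # occupied fraction of the radial pitch
    mucosa_frac: float = 0.38   # mucosal share of the pitch
    submucosa_frac: float = 0.10
    n_arcs: int = 3             # involved arcs planted per slide
    stripe_dt: float = 0.07     # arc-length width of uninvolved texture stripes

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("raster size must be >= 64")
        if self.mucosa_frac + self.submucosa_frac >= self.band_frac:
            raise ValueError("mucosa + submucosa stripes must fit inside the band")
        r_max = 0.47 * self.size
        if r_max / self.turns < 8:
            raise ValueError("spiral pitch too small for the raster")


@dataclass
class SlideRecord:
    """One mouse's slide: raster, metadata and (synthetic) truth mask."""

    mouse_id: str
    model_name: str
    clinical_score: int
    image: np.ndarray                     # H x W x 3 uint8
    truth_mask: np.ndarray | None = None  # H x W uint8 class ids
    involved_fraction: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.clinical_score <= 12:
            raise ValueError("clinical_score must lie in [0, 12]")
        if self.truth_mask is not None and self.truth_mask.shape != self.image.shape[:2]:
            raise ValueError("image and truth_mask dimensions must match")


def sample_clinical_score(involved_fraction: float, noise_sd: float, seed: int) -> int:
    """Clinical score (0-12 Cooper-style composite) coupled to involvement.

    score = round(clip(12*f + eps, 0, 12)) with eps ~ Normal(0, noise_sd).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    return int(round(float(np.clip(12.0 * involved_fraction + eps, 0.0, 12.0))))


def _spiral_fields(geom: SpiralGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel (region, arc_pos, mucosa_mask) for the spiral layout.

    region codes: 0 background, 1 muscle, 2 submucosa, 3 mucosa.
    arc_pos is normalized spiral arc-length in [0, 1], 0 = centre = proximal.
    """
    n = geom.size
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    r_max = 0.47 * n
    pitch = r_max / geom.turns
    s = r / pitch - theta / (2 * np.pi)
    turn = np.floor(s)
    u = s - turn                       # position across the pitch, [0, 1)
    theta_tot = 2 * np.pi * (turn + theta / (2 * np.pi))
    theta_lim = 2 * np.pi * geom.turns
    in_spiral = (turn >= 0) & (theta_tot < theta_lim) & (r <= r_max)

    region = np.zeros((n, n), dtype=np.uint8)
    mucosa = in_spiral & (u < geom.mucosa_frac)
    submuc = in_spiral & (u >= geom.mucosa_frac) & (u < geom.mucosa_frac + geom.submucosa_frac)
    muscle = in_spiral & (u >= geom.mucosa_frac + geom.submucosa_frac) & (u < geom.band_frac)
    region[muscle] = 1
    region[submuc] = 2
    region[mucosa] = 3
    # arc length of an Archimedean spiral grows ~ theta^2
    arc_pos = np.clip((theta_tot / theta_lim) ** 2, 0.0, 1.0)
    return region, arc_pos, mucosa


def _eligible_window(pattern: str) -> tuple[float, float]:
    if pattern == "proximal_sparing":
        return 0.5, 1.0
    return 0.0, 1.0


def _plant_involved(arc_pos: np.ndarray, mucosa: np.ndarray, profile: ModelProfile,
                    geom: SpiralGeometry, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of involved mucosal pixels hitting the target fraction."""
    target = profile.involved_fraction_mean
    if target <= 0:
        return np.zeros_like(mucosa)
    t = arc_pos[mucosa]
    lo, hi = _eligible_window(profile.injury_pattern)
    centers = rng.uniform(lo, hi, size=geom.n_arcs)
    if profile.injury_pattern == "proximal_involving":
        centers[0] = rng.uniform(0.05, 0.40)   # guarantee proximal involvement

    def frac_at(width: float) -> np.ndarray:
        hit = np.zeros(t.shape, dtype=bool)
        for c in centers:
            a, b = max(c - width, lo), min(c + width, hi)
            hit |= (t >= a) & (t <= b)
        return hit

    # realized fraction is monotone in the common arc half-width: bisect
    w_lo, w_hi = 0.0, hi - lo
    for _ in range(50):
        w = 0.5 * (w_lo + w_hi)
        if frac_at(w).mean() < target:
            w_lo = w
        else:
            w_hi = w
    hit = frac_at(w_hi)
    mask = np.zeros_like(mucosa)
    mask[mucosa] = hit
    return mask


def generate_slide(profile: ModelProfile, geometry: SpiralGeometry | None = None,
                   seed: int = 0, *, score_noise_sd: float = 1.0,
                   mouse_id: str | None = None) -> SlideRecord:
    """Render one synthetic swiss-roll slide with truth mask and metadata."""
    geom = geometry or SpiralGeometry()
    rng = np.random.default_rng(seed)
    region, arc_pos, mucosa = _spiral_fields(geom)

    # fraction is itself slide-to-slide variable around the model mean
    # slide-to-slide variability, clipped so the realized fraction stays
    # within +-0.1 of the model mean (the generator's composition contract)
    frac = profile.involved_fraction_mean
    if frac > 0 and profile.involved_fraction_sd > 0:
        draw = rng.normal(frac, profile.involved_fraction_sd)
        frac = float(np.clip(draw, max(frac - 0.09, 0.02),
                             min(frac + 0.09, 0.98)))
    slide_profile = replace(profile, involved_fraction_mean=frac) if frac != profile.involved_fraction_mean else profile

    involved = _plant_involved(arc_pos, mucosa, slide_profile, geom, rng)

    mask = np.full(region.shape, class_id("Background"), dtype=np.uint8)
    mask[region == 1] = class_id("Muscle")
    mask[region == 2] = class_id("Submucosa")

    # uninvolved mucosa: arc-length stripes, class drawn from the profile mix
    unin = mucosa & ~involved
    t_all = arc_pos
    n_stripes = max(1, int(np.ceil(1.0 / geom.stripe_dt)))
    stripe_cls = rng.choice(len(UNINVOLVED_CLASSES), size=n_stripes,
                            p=np.asarray(profile.uninvolved_class_mix))
    stripe_idx = np.minimum((t_all / geom.stripe_dt).astype(int), n_stripes - 1)
    for si in range(n_stripes):
        sel = unin & (stripe_idx == si)
        if sel.any():
            mask[sel] = class_id(UNINVOLVED_CLASSES[stripe_cls[si]])

    # involved mucosa: contiguous chunks along arc length, sized by the mix
    if involved.any():
        iy, ix = np.nonzero(involved)
        order = np.argsort(t_all[iy, ix], kind="stable")
        iy, ix = iy[order], ix[order]
        counts = np.floor(np.cumsum(profile.involved_class_mix) * iy.size).astype(int)
        start = 0
        for ci, stop in enumerate(counts):
            mask[iy[start:stop], ix[start:stop]] = class_id(INVOLVED_CLASSES[ci])
            start = stop

    # compose the RGB image from per-class full-size textures
    img = np.empty(mask.shape + (3,), dtype=np.uint8)
    tex_seed = int(rng.integers(0, 2**31 - 1))
    for cid in np.unique(mask):
        sel = mask == cid
        tex = render_texture(CLASS_ORDER[cid], mask.shape, tex_seed)
        img[sel] = tex[sel]

    realized = float(involved.sum() / max(mucosa.sum(), 1))
    score = sample_clinical_score(realized, score_noise_sd,
                                  int(rng.integers(0, 2**31 - 1)))
    return SlideRecord(
        mouse_id=mouse_id or f"{profile.model_name}_{seed}",
        model_name=profile.model_name,
        clinical_score=score,
        image=img,
        truth_mask=mask,
        involved_fraction=realized,
    )


def generate_cohort(profiles: list[tuple[ModelProfile, int]], seed: int,
                    geometry: SpiralGeometry | None = None,
                    score_noise_sd: float = 1.0) -> list[SlideRecord]:
    """Generate ``count`` slides per profile with per-slide seeds derived
    deterministically from the cohort seed."""
    if not profiles:
        raise ValueError("profile list must not be empty")
    for _, count in profiles:
        if count < 1:
            raise ValueError("per-profile counts must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(sum(c for _, c in profiles)))
    slides: list[SlideRecord] = []
    for profile, count in profiles:
        for i in range(count):
            child = next(children)
            slide_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
            rec = generate_slide(
                profile, geometry, slide_seed,
                score_noise_sd=score_noise_sd,
                mouse_id=f"{profile.model_name}_{i:02d}",
            )
            slides.append(rec)
    return slides


def default_cohort_profiles(n_per_model: int = 2) -> list[tuple[ModelProfile, int]]:
    """The standard four-model cohort layout."""
    return [(DEFAULT_PROFILES[m], n_per_model) for m in MODEL_NAMES]


def write_cohort(slides: list[SlideRecord], out_dir: str | Path,
                 config: dict | None = None) -> pd.DataFrame:
    """Write slides as PNG, truth masks as single-channel PNG, metadata as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in slides:
        img_path = out / f"{rec.mouse_id}.png"
        iio.imwrite(img_path, rec.image)
        mask_path = ""
        if rec.truth_mask is not None:
            mask_path = str(out / f"{rec.mouse_id}_mask.png")
            iio.imwrite(mask_path, rec.truth_mask)
        rows.append({
            "mouse_id": rec.mouse_id,
            "model": rec.model_name,
            "clinical_score": rec.clinical_score,
            "path": str(img_path),
            "mask_path": mask_path,
        })
    meta = pd.DataFrame(rows)
    meta.to_csv(out / "metadata.csv", index=False)
    if config is not None:
        (out / "cohort.yaml").write_text(yaml.safe_dump(config))
    return meta


def read_cohort(in_dir: str | Path) -> list[SlideRecord]:
    """Load a cohort previously written by :func:`write_cohort`."""
    meta = pd.read_csv(Path(in_dir) / "metadata.csv")
    slides = []
    for row in meta.itertuples():
        mask = None
        if isinstance(row.mask_path, str) and row.mask_path:
            mask = iio.imread(row.mask_path)
        slides.append(SlideRecord(
            mouse_id=row.mouse_id, model_name=row.model,
            clinical_score=int(row.clinical_score),
            image=iio.imread(row.path), truth_mask=mask,
        ))
    return slides
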