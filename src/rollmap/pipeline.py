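"""End-to-end experiment orchestration on synthetic cohorts.

Glues the stages together at desk scale: cohort generation, patch
sampling, two-phase classifier training with pseudo-label refinement,
truth-mask oracle prediction, class proportions, and phenotype LDA.
Problem sizes default to a few hundred patches per mouse on 512 px slides
so full experiments run in seconds to minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import involved as inv
from . import phenotype as ph
from .discovery import class_proportions
from .patching import PatchRef
from .synthetic import (DEFAULT_PROFILES, ModelProfile, SlideRecord,
                        SpiralGeometry, generate_cohort)
from .textures import (CLASS_ORDER, INVOLVED_CLASSES, MUCOSAL_CLASSES,
                       NON_MUCOSA_CLASSES, UNINVOLVED_CLASSES, class_id)


def _window_sum(integral: np.ndarray, y: np.ndarray, x: np.ndarray,
                size: int) -> np.ndarray:
    return (integral[y + size, x + size] - integral[y, x + size]
            - integral[y + size, x] + integral[y, x])


def _integral(mask: np.ndarray) -> np.ndarray:
    out = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    out[1:, 1:] = mask.astype(np.int64).cumsum(0).cumsum(1)
    return out


@dataclass
class PatchSample:
    """Sampled patches from one slide with truth annotations."""

    refs: list[PatchRef]
    images: np.ndarray            # (n, size, size, 3)
    truth_involvement: np.ndarray  # Involved / Uninvolved per patch
    truth_class: np.ndarray        # dominant mucosal texture name per patch
    truth_involved_class: np.ndarray  # dominant involved texture ('' if none)


def sample_mucosal_patches(record: SlideRecord, size: int = 64, n: int = 60,
                           seed: int = 0, min_mucosa: float = 0.3) -> PatchSample:
    """Sample ``n`` patches whose windows are mostly mucosa, with truth labels.

    A patch's truth involvement is ``Involved`` when involved textures make
    up more than half of its mucosal pixels; its truth class is the modal
    mucosal texture in the window.
    """
    mask = record.truth_mask
    if mask is None:
        raise ValueError("slide has no truth mask")
    h, w = mask.shape
    mucosa = np.isin(mask, [class_id(c) for c in MUCOSAL_CLASSES])
    involved = np.isin(mask, [class_id(c) for c in INVOLVED_CLASSES])
    I_muc, I_inv = _integral(mucosa), _integral(involved)
    rng = np.random.default_rng(seed)
    refs: list[PatchRef] = []
    n_try = 0
    while len(refs) < n and n_try < 200:
        n_try += 1
        ys = rng.integers(0, h - size + 1, size=4 * n)
        xs = rng.integers(0, w - size + 1, size=4 * n)
        muc = _window_sum(I_muc, ys, xs, size) / (size * size)
        for y, x in zip(ys[muc >= min_mucosa], xs[muc >= min_mucosa]):
            refs.append(PatchRef(record.mouse_id, int(x), int(y), size, "grid"))
            if len(refs) == n:
                break
    if len(refs) < n:
        raise ValueError(
            f"could not find {n} mucosal patches on {record.mouse_id}")
    ys = np.array([r.y for r in refs])
    xs = np.array([r.x for r in refs])
    muc_px = _window_sum(I_muc, ys, xs, size)
    inv_px = _window_sum(I_inv, ys, xs, size)
    truth_inv = np.where(inv_px > 0.5 * muc_px, inv.INVOLVED_LABEL,
                         inv.UNINVOLVED_LABEL)
    images = np.stack([r.window(record.image) for r in refs])
    truth_cls, truth_inv_cls = [], []
    inv_ids = [class_id(c) for c in INVOLVED_CLASSES]
    for r in refs:
        win = r.window(mask)[::4, ::4].ravel()
        counts = np.bincount(win, minlength=len(CLASS_ORDER))
        for cid in (class_id(c) for c in NON_MUCOSA_CLASSES):
            counts[cid] = 0
        truth_cls.append(CLASS_ORDER[int(counts.argmax())])
        inv_counts = counts[inv_ids]
        truth_inv_cls.append(INVOLVED_CLASSES[int(inv_counts.argmax())]
                             if inv_counts.sum() else "")
    return PatchSample(refs, images, truth_inv, np.asarray(truth_cls),
                       np.asarray(truth_inv_cls))


def tissue_map_geometry(size: int = 1024) -> SpiralGeometry:
    """Spiral layout with stripes thick enough that 32 px blocks fit inside
    each tissue category (used for tissue-classifier experiments)."""
    return SpiralGeometry(size=size, turns=1.6, band_frac=0.62,
                          mucosa_frac=0.28, submucosa_frac=0.15)


def sample_tissue_blocks(record: SlideRecord, n_per_class: int = 100,
                         seed: int = 0, block_size: int = 32,
                         purity: float = 0.85) -> tuple[np.ndarray, np.ndarray]:
    """Sample labelled 32x32 blocks for tissue-classifier training.

    Blocks are drawn uniformly over truth regions; a block is labelled with
    a tissue class ({Background, Muscle, Tissue, Submucosa}; Tissue = any
    mucosal texture) when that class covers >= ``purity`` of its pixels.
    Requires stripes at least block-sized (see :func:`tissue_map_geometry`).
    """
    from .tissue import TISSUE_CLASSES
    mask = record.truth_mask
    if mask is None:
        raise ValueError("slide has no truth mask")
    h, w = mask.shape
    cat_masks = {
        "Background": mask == class_id("Background"),
        "Muscle": mask == class_id("Muscle"),
        "Submucosa": mask == class_id("Submucosa"),
        "Tissue": np.isin(mask, [class_id(c) for c in MUCOSAL_CLASSES]),
    }
    rng = np.random.default_rng(seed)
    X, y = [], []
    for name in TISSUE_CLASSES:
        I = _integral(cat_masks[name])
        found = 0
        for _ in range(400):
            if found >= n_per_class:
                break
            ys = rng.integers(0, h - block_size + 1, size=4 * n_per_class)
            xs = rng.integers(0, w - block_size + 1, size=4 * n_per_class)
            cov = _window_sum(I, ys, xs, block_size) / (block_size ** 2)
            for yy, xx in zip(ys[cov >= purity], xs[cov >= purity]):
                X.append(record.image[yy:yy + block_size, xx:xx + block_size])
                y.append(name)
                found += 1
                if found >= n_per_class:
                    break
        if found < n_per_class:
            raise ValueError(
                f"could not sample {n_per_class} pure {name} blocks on "
                f"{record.mouse_id}")
    return np.stack(X), np.asarray(y)


def truth_tissue_map(record: SlideRecord, block_size: int = 32):
    """Tissue map derived from the truth mask (majority vote per block);
    the oracle counterpart of a trained tissue classifier."""
    from .tissue import TISSUE_CLASSES, TissueMap
    mask = record.truth_mask
    if mask is None:
        raise ValueError("slide has no truth mask")
    h, w = mask.shape
    gh, gw = int(np.ceil(h / block_size)), int(np.ceil(w / block_size))
    tissue_cat = np.full(mask.shape, TISSUE_CLASSES.index("Background"),
                         dtype=np.uint8)
    for name in ("Muscle", "Submucosa"):
        tissue_cat[mask == class_id(name)] = TISSUE_CLASSES.index(name)
    muc = np.isin(mask, [class_id(c) for c in MUCOSAL_CLASSES])
    tissue_cat[muc] = TISSUE_CLASSES.index("Tissue")
    padded = np.zeros((gh * block_size, gw * block_size), dtype=np.uint8)
    padded[:h, :w] = tissue_cat
    blocks = (padded.reshape(gh, block_size, gw, block_size)
              .transpose(0, 2, 1, 3).reshape(gh * gw, -1))
    grid = np.array([np.bincount(b, minlength=4).argmax() for b in blocks],
                    dtype=np.uint8).reshape(gh, gw)
    return TissueMap(grid=grid, slide_dims=(h, w), block_size=block_size)


def oracle_confidence(record: SlideRecord, ref: PatchRef) -> float:
    """Truth-mask oracle: Involved confidence = involved share of the
    patch's mucosal pixels (0.5 when the window has no mucosa)."""
    win = ref.window(record.truth_mask)
    muc = np.isin(win, [class_id(c) for c in MUCOSAL_CLASSES])
    if not muc.any():
        return 0.5
    invp = np.isin(win, [class_id(c) for c in INVOLVED_CLASSES])
    return float(invp.sum() / muc.sum())


def _cohort_patches(slides, size, n_per_slide, seed, min_mucosa=0.3):
    samples = {}
    ss = np.random.SeedSequence(seed)
    for rec, child in zip(slides, ss.spawn(len(slides))):
        child_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        samples[rec.mouse_id] = sample_mucosal_patches(
            rec, size=size, n=n_per_slide, seed=child_seed,
            min_mucosa=min_mucosa)
    return samples


def _gather(samples, mouse_ids):
    X, t_inv, t_cls, mids = [], [], [], []
    for m in mouse_ids:
        s = samples[m]
        X.append(s.images)
        t_inv.append(s.truth_involvement)
        t_cls.append(s.truth_class)
        mids.extend([m] * len(s.refs))
    return (np.concatenate(X), np.concatenate(t_inv), np.concatenate(t_cls),
            np.asarray(mids))


def two_phase_profiles(involved_fraction: float = 0.6,
                       involved_class_mix: tuple[float, ...] = (0.5, 0.5, 0, 0)
                       ) -> list[tuple[ModelProfile, int]]:
    """Eight-mouse cohort (2 control + 2 per colitis model) with a common
    involved-area fraction for the colitis slides.

    The default plants three uninvolved and two involved texture classes,
    matching the k = 5 used for pseudo-label refinement (one cluster per
    texture group).
    """
    from dataclasses import replace
    out: list[tuple[ModelProfile, int]] = [(DEFAULT_PROFILES["Control"], 2)]
    for name in ("KLF5", "DSS", "Combined"):
        out.append((replace(DEFAULT_PROFILES[name],
                            involved_fraction_mean=involved_fraction,
                            involved_class_mix=involved_class_mix), 2))
    return out


def run_two_phase_experiment(seed: int, slide_size: int = 512,
                             patch_size: int = 48, patches_per_slide: int = 160,
                             k: int = 5, epochs: int = 45,
                             feature_width: int = 256,
                             min_mucosa: float = 0.5) -> dict:
    """Full two-phase training run on a synthetic 8-mouse cohort.

    Returns phase-1 and phase-2 held-out weighted F1 against truth
    involvement, plus the refined-label agreement with truth on the
    training mice.
    """
    rng_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
    slides = generate_cohort(two_phase_profiles(), seed=rng_seed,
                             geometry=SpiralGeometry(size=slide_size, turns=2.5))
    ids = [s.mouse_id for s in slides]
    models = [s.model_name for s in slides]
    split = inv.split_cohort(ids, models, seed=rng_seed)
    samples = _cohort_patches(slides, patch_size, patches_per_slide, rng_seed,
                              min_mucosa=min_mucosa)
    status = {s.mouse_id: (inv.CONTROL if s.model_name == "Control"
                           else inv.COLITIS) for s in slides}

    X_tr, t_inv_tr, _, mid_tr = _gather(samples, split.train)
    y1_tr = np.asarray([status[m] for m in mid_tr])
    if split.validation:
        X_val, t_inv_val, _, mid_val = _gather(samples, split.validation)
    else:  # carve a patch-level validation slice out of train
        r = np.random.default_rng(rng_seed)
        idx = r.permutation(len(X_tr))
        n_val = max(1, len(X_tr) // 10)
        X_val, mid_val = X_tr[idx[:n_val]], mid_tr[idx[:n_val]]
        t_inv_val = t_inv_tr[idx[:n_val]]
        X_tr, mid_tr = X_tr[idx[n_val:]], mid_tr[idx[n_val:]]
        t_inv_tr = t_inv_tr[idx[n_val:]]
        y1_tr = np.asarray([status[m] for m in mid_tr])
    y1_val = np.asarray([status[m] for m in mid_val])
    X_te, t_inv_te, _, _ = _gather(samples, split.test)

    config = {"epochs": epochs, "feature_width": feature_width}
    phase1 = inv.train_patch_classifier(X_tr, y1_tr, config, seed=rng_seed,
                                        val_patches=X_val, val_labels=y1_val)
    p1_pred = np.where(phase1.predict(X_te) == inv.COLITIS,
                       inv.INVOLVED_LABEL, inv.UNINVOLVED_LABEL)
    from sklearn.metrics import f1_score
    phase1_f1 = float(f1_score(t_inv_te, p1_pred, average="weighted"))

    feats = inv.extract_features(phase1, X_tr)
    relabeler = inv.cluster_and_relabel(
        feats, mid_tr, [status[m] for m in mid_tr], k=k, seed=rng_seed)
    refined = relabeler.refined_labels_
    relabel_acc = float((refined == t_inv_tr).mean())

    # refine validation labels through the fitted cluster model
    val_assign = relabeler.kmeans_.predict(
        inv.extract_features(phase1, X_val))
    y2_val = np.where(
        np.asarray([status[m] for m in mid_val]) == inv.CONTROL,
        inv.UNINVOLVED_LABEL,
        [relabeler.cluster_labels_[a] for a in val_assign])

    phase2 = inv.train_patch_classifier(X_tr, refined, config, seed=rng_seed,
                                        val_patches=X_val, val_labels=y2_val)
    phase2_f1 = inv.evaluate_patch_model(phase2, X_te, t_inv_te)["overall_f1"]
    return {
        "phase1_f1": phase1_f1,
        "phase2_f1": float(phase2_f1),
        "relabel_accuracy": relabel_acc,
        "n_train_patches": len(X_tr),
        "n_test_patches": len(X_te),
        "phase1_model": phase1,
        "phase2_model": phase2,
        "relabeler": relabeler,
        "samples": samples,
        "split": split,
        "slides": slides,
    }


def run_phenotype_experiment(seed: int, n_per_model: int = 10,
                             slide_size: int = 384, patch_size: int = 48,
                             patches_per_slide: int = 80,
                             score_noise_sd: float = 1.0) -> dict:
    """Cohort-level phenotype prediction with the truth-mask oracle predictor.

    Generates a four-model cohort, derives per-mouse proportion features
    from oracle patch calls, fits mouse-model and score-bin LDA classifiers
    with a mouse-level held-out split, and correlates InvolvedProportion
    with clinical score.
    """
    rng_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
    profiles = [(DEFAULT_PROFILES[m], n_per_model)
                for m in ("Control", "KLF5", "DSS", "Combined")]
    slides = generate_cohort(profiles, seed=rng_seed,
                             geometry=SpiralGeometry(size=slide_size, turns=2.5),
                             score_noise_sd=score_noise_sd)
    samples = _cohort_patches(slides, patch_size, patches_per_slide, rng_seed)

    calls = []
    for rec in slides:
        s = samples[rec.mouse_id]
        for t_inv, t_cls in zip(s.truth_involvement, s.truth_involved_class):
            call = t_cls if t_inv == inv.INVOLVED_LABEL else inv.UNINVOLVED_LABEL
            calls.append({"mouse_id": rec.mouse_id, "call": call})
    props = class_proportions(pd.DataFrame(calls), INVOLVED_CLASSES)

    meta = pd.DataFrame({
        "mouse_id": [s.mouse_id for s in slides],
        "model": [s.model_name for s in slides],
        "clinical_score": [s.clinical_score for s in slides],
        "involved_fraction": [s.involved_fraction for s in slides],
    }).set_index("mouse_id")
    props = props.loc[meta.index]

    split = inv.split_cohort(meta.index, meta["model"],
                             fractions=(0.7, 0.0, 0.3), seed=rng_seed)
    tr, te = list(split.train), list(split.test)
    X_tr, X_te = props.loc[tr].to_numpy(), props.loc[te].to_numpy()

    model_lda = ph.train_lda(X_tr, meta.loc[tr, "model"])
    model_eval = ph.evaluate_phenotype(model_lda.predict(X_te),
                                       meta.loc[te, "model"])

    bins = meta["clinical_score"].map(ph.bin_score)
    bin_lda = ph.train_lda(X_tr, bins.loc[tr])
    bin_eval = ph.evaluate_phenotype(bin_lda.predict(X_te), bins.loc[te])

    involved_prop = 1.0 - props["Uninvolved"]
    r2 = ph.correlate_involvement(involved_prop, meta["clinical_score"])
    # analytic benchmark implied by the score generator:
    # score ~ 12 f + eps  =>  R^2 = Var(12 f) / (Var(12 f) + noise_sd^2)
    var12f = float(np.var(12.0 * meta["involved_fraction"].to_numpy()))
    r2_analytic = var12f / (var12f + score_noise_sd ** 2)
    return {
        "model_weighted_f1": model_eval["weighted_f1"],
        "model_accuracy": model_eval["accuracy"],
        "bin_accuracy": bin_eval["accuracy"],
        "bin_weighted_f1": bin_eval["weighted_f1"],
        "r2": r2,
        "r2_analytic": float(r2_analytic),
        "proportions": props,
        "metadata": meta,
        "model_lda": model_lda,
        "bin_lda": bin_lda,
        "n_mice": len(slides),
    }
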