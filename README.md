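# rollmap

Patch-based detection, mapping and quantification of **involved** (diseased)
versus **uninvolved** (healthy) histology in swiss-rolled mouse colon slides,
and prediction of colitis phenotype from the resulting patch-class
composition.

## Who this is for

Groups characterizing colitis mouse models (chemically induced DSS colitis,
inducible epithelial knockouts such as *Klf5*, or combinations) from
H&E-stained swiss-roll whole-slide images. A swiss roll coils the entire
colon onto one slide with the proximal end at the spiral centre, so a single
image captures the full proximal→distal injury distribution. `rollmap`
automates what a pathologist would otherwise score by hand: *where* the
colon is involved, *how much* of it is involved, and *what kinds* of injury
are present.

## The method

1. **Tiling and tissue filtering.** Slides (downsampled ×8) are tiled into
   224×224 patches. A small 4-class classifier over 32×32 blocks
   ({Background, Muscle, Tissue, Submucosa}) builds a per-slide *tissue
   map*; patches whose area is more than 65% Background/Muscle are dropped.
2. **Two-phase involvement classifier with pseudo-label refinement.**
   Phase 1 trains a patch classifier on slide-level labels (every patch of a
   colitis mouse labelled `Colitis`, every control patch `Control`). Because
   colitis colons retain healthy mucosa, many phase-1 labels are wrong at
   patch level. The phase-1 network's penultimate embedding is therefore
   clustered with k-means (k = 5), and each cluster is relabelled
   `Involved`/`Uninvolved` by an enrichment rule: a cluster is Involved iff
   its mean per-mouse proportion in control mice is below τ = 0.05 and below
   its proportion in colitis mice. Phase 2 retrains on these refined
   patch-level labels.
3. **Overlays.** The final classifier is applied to a dense lattice of
   overlapping patches (offsets of 20 px, 10 steps in each direction: 441
   candidates per grid patch, ~450 → ~200,000 patches per mouse).
   Confidences are averaged per pixel; pixels with mean Involved confidence
   strictly above 50% are painted red, other covered tissue pixels green,
   and Background/Muscle regions are masked. The slide's
   **InvolvedProportion** is the Involved share of prediction pixels.
4. **Patch-class discovery.** Involved and uninvolved patch embeddings are
   reduced by PCA to the smallest component count capturing 95% of variance
   and clustered with k-means (4 involved classes, 3 uninvolved classes).
5. **Phenotype prediction.** Per-mouse proportion features (Uninvolved
   share + one share per involved class, summing to 1) feed linear
   discriminant analysis (LDA, Ledoit–Wolf shrinkage) classifiers for the
   mouse model and for the clinical-score bin (Low = 0–2, Mid = 3–7,
   High = 8–12 on the 0–12 composite score), and InvolvedProportion is
   correlated with the raw clinical score (R²).

A seeded **synthetic swiss-roll generator** renders Archimedean-spiral
slides with procedural textures for ten tissue classes, model-specific
injury patterns (DSS-like proximal sparing, knockout-like proximal
involvement), and clinical scores coupled to the involved-area fraction —
so the entire pipeline is testable end to end with no slide data.

## Worked example

```python
from rollmap import run_two_phase_experiment

res = run_two_phase_experiment(seed=2)
print(f"phase-1 F1 {res['phase1_f1']:.3f}  "
      f"phase-2 F1 {res['phase2_f1']:.3f}  "
      f"refined-label accuracy {res['relabel_accuracy']:.3f}")
```

prints

```
phase-1 F1 0.541  phase-2 F1 0.943  refined-label accuracy 0.957
```

— on an 8-mouse synthetic cohort whose colitis slides are 60% involved
texture, the phase-1 classifier (trained on slide-level labels) reaches
only 0.54 held-out F1 against true patch involvement, because it calls the
healthy 40% of colitis slides "Colitis". Pseudo-label refinement corrects
95.7% of training labels, and the phase-2 classifier trained on them
reaches 0.94 — the pipeline's central claim, that cluster-based label
refinement turns slide labels into accurate patch-level supervision.

The same experiments are available from a shell:

```bash
rollmap cohort --out cohort_dir --seed 0     # write a synthetic cohort
rollmap two-phase --seed 2                   # the run shown above
rollmap phenotype --seed 7                   # proportion-feature LDA run
```

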