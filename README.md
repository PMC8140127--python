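# cmhseg

Detection and quantification of **cerebral microhemorrhages (CMHs)** in
Prussian blue-stained brain histology. CMHs appear in sections stained with
Perl's Prussian blue as blue hemosiderin (iron) deposits on a pink Nuclear
Fast Red counterstain; quantifying them by hand is slow and subjective.
`cmhseg` implements two spectroscopic, calibration-light segmentation
approaches for RGB brightfield images, the physically calibrated
post-processing filter chain, multi-annotator consensus ground-truthing,
and the agreement statistics used to evaluate them — plus a seeded
synthetic-histology generator so the whole pipeline can be exercised and
tested without any microscope data.

Intended users: researchers quantifying iron-positive deposits (or any
blue-on-pink chromogen) in calibrated RGB histology images.

## Methods in brief

**Ratiometric segmentation.** Each pixel is scored with the segmentation
ratio

    ratio = I_R · I_G / I_B²

which is ≪ 1 for blue-dominant (Prussian blue) pixels, ≈ 1 for achromatic
pixels, and > 1 for the red-dominant counterstain; pixels *below* a
threshold are segmented. The ratio is invariant to uniform intensity
scaling. The threshold is calibrated against ground truth: per image, the
grid value minimizing the absolute percent error of the post-processed
segmented area, then the **median** across images.

**RGB spectral-phasor segmentation.** Each pixel's channel intensities
(l = 1 red, 2 green, 3 blue) are projected onto the first Fourier harmonic,

    H = Σ_l I_l cos(2πl/3),    S = Σ_l I_l sin(2πl/3),

after normalization by the pixel sum, giving a chromaticity coordinate
inside the triangle of pure-channel vertices on the unit circle (blue at
(1, 0)). A 2-D phasor histogram is built, the "bluest" occupied bin is
found by minimizing the row/column index ratio x/y, and a circular gate
centred there remaps enclosed pixels to an image-space mask. The gate
radius is calibrated like the threshold, but with the **mean** of the
per-image optima.

**Post-processing chain** (strict inequalities, physical units): remove
components < 5 µm²; remove components < 50 µm² farther than 50 µm from the
nearest other component; remove components > 6000 µm² (ratiometric/phasor
only); fill enclosed holes < 1.73 µm² (phasor only); optional intersection
with a coarse manual ROI.

**Evaluation.** Consensus ground truth by per-pixel majority vote (≥ 2 of
4 annotators); pixel-pooled sensitivity/specificity and ROC/AUC (swept
after the first two filter steps); Dice overlap; single-measure two-way
random-effects absolute-agreement ICC(A,1) with McGraw–Wong 95% CI; and
Bland–Altman mean percent difference with 95% limits of agreement.

## Worked example

```python
import numpy as np
from cmhseg import (SyntheticSpec, FilterChainSpec, generate_dataset,
                    majority_vote, run_chain, select_optimal_threshold,
                    roc_sweep, dice)
from cmhseg import ratiometric

spec = SyntheticSpec(n_shadows=1)           # 384×384 px at 0.5 µm/px
records = generate_dataset(8, spec, seed=1)
images = [r.image for r in records]
gts = [run_chain(majority_vote(r.annotations), FilterChainSpec(method="truth"))
       for r in records]

sel = select_optimal_threshold(images, gts)
print("optimal threshold:", round(sel.optimal_threshold, 3))

curve = roc_sweep(images, gts, ratiometric.segment_image,
                  ratiometric.default_threshold_grid())
print("ratiometric AUC:", round(curve.auc, 3))

masks = [run_chain(ratiometric.segment_image(im, sel.optimal_threshold),
                   FilterChainSpec(method="ratiometric")) for im in images]
print("mean Dice vs truth:",
      round(float(np.mean([dice(m, r.truth) for m, r in zip(masks, records)])), 3))
```

Output:

```
optimal threshold: 0.307
ratiometric AUC: 0.995
mean Dice vs truth: 0.971
```

The threshold lands between the deposit ratio distribution (median ≈ 0.09
under the default color model) and the background's (median ≈ 1.06); the
AUC and Dice say the calibrated segmenter recovers the generator's truth
masks nearly pixel-perfectly, with residual disagreement confined to the
anti-aliased deposit boundaries.

The same workflow is available from the shell:

```bash
cmh synth --n 20 --seed 7 --out data/ --shadows
cmh vote --pixel-size 0.5 data/synthetic_000_annotator*.png consensus.png
cmh calibrate-ratio --images data/ --truth data/ --pixel-size 0.5
cmh segment --method ratio --threshold 0.31 --pixel-size 0.5 \
    data/synthetic_000.png seg.png
cmh evaluate --pred preds/ --truth data/ --pixel-size 0.5 --report report.csv
```

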