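# Methods notes

## Problem and model

Prussian blue histochemistry renders ferric iron deposits (hemosiderin,
the residue of cerebral microhemorrhages) blue against a pink Nuclear Fast
Red counterstain. Both segmenters in this package exploit the resulting
chromatic separation in calibrated RGB brightfield images; neither uses
spatial texture, so both are cheap, microscope-portable, and depend on a
single scalar parameter that is calibrated against annotated ground truth.

### Ratiometric statistic

The per-pixel score is `ratio = I_R·I_G/I_B²`. Its useful properties:

* blue-dominant pixels score ≪ 1, achromatic pixels score exactly 1, and
  the red-dominant counterstain scores > 1, so a single threshold in
  (0, 1] separates deposit from background and rejects grey shadows;
* the statistic is dimensionless and invariant to uniform scaling of all
  three channels (exposure, lamp brightness), since c² cancels;
* pixels with `I_B = 0` cannot be Prussian blue (the stain is bright in
  the blue channel), so they are assigned a large sentinel (1e12) that no
  reasonable threshold reaches. This also covers pure black pixels, which
  would otherwise be 0/0.

Thresholding is strict (`ratio < t`). The default calibration grid is a
geometric grid of 101 values over [0.05, 5.0]: geometric because the ratio
is a product of intensities and its useful resolution is relative, wide
enough to bracket both stain distributions on either side of 1.

### Spectral phasor

Channel intensities are treated as a 3-sample spectrum and projected onto
the first discrete Fourier harmonic over the channel index l = 1, 2, 3,
giving `H = Σ I_l cos(2πl/3)` and `S = Σ I_l sin(2πl/3)`. Intensities are
first divided by the per-pixel total (zero-total pixels map to the
origin). The literal unnormalized projection is available
(`normalize=False`), but normalization is the default because gating a
*fixed* circular region of phasor space only makes sense on
intensity-independent coordinates: normalized phasors live inside the
equilateral triangle with vertices red (−½, +√3/2), green (−½, −√3/2),
blue (1, 0) on the unit circle, so histogram axes can be fixed at
[−1, 1]².

The phasor histogram is 256×256 with a fixed orientation: rows (1-based
index x) run from S = +1 at row 1 down to S = −1, columns (index y) from
H = −1 up to +1. The "bluest" occupied bin minimizes x/y over 1-based
indices; with this orientation, minimizing x/y drives the search toward
large H (blue) and away from the counterstain's positive-S cluster. Ties
break toward larger y, then smaller x (bluer first). The axis ordering and
resolution are package conventions — the criterion is only meaningful
relative to a declared matrix layout — and are therefore documented rather
than configurable defaults scattered through the code.

The gate is circular in phasor units (bins are square, so bin-index and
phasor-unit circles coincide), inclusive at the boundary, and its radius
is swept over 40 values in (0, 0.5]: 0.5 is half the triangle's
circumradius, beyond which the gate starts swallowing the counterstain
cluster wholesale.

A deliberate property of the bluest-bin criterion: it frequently selects a
sparsely populated extreme bin at the tail of the deposit cluster rather
than its mode, displacing the gate centre by a few tenths of a phasor
unit. The per-image radius calibration absorbs this, but it makes the
phasor method's per-image optima noisier than the ratiometric method's —
the phasor approach is the less precise of the two, and the agreement
statistics show it.

## Filter chain

All filters work on physical areas/distances, so a pixel-size calibration
(µm per pixel edge) is required everywhere; there is deliberately no
default. Defaults (5, 50 µm² / 50 µm, 6000 µm², 1.73 µm²) are the
empirically chosen values of the study protocol; inequalities are strict
exactly as stated ("less than 5", "larger than 6000"). Choices the
protocol leaves open:

* **Inter-region distance** is the minimum Euclidean distance between
  boundary-pixel centres (computed via a KD-tree); boundary distance is
  conservative relative to centroid distance when the neighbour is large.
* **A single-region image** keeps its region: the isolation rule targets
  scattered speckle and is vacuous when no "closest spot" exists.
* **Connectivity** is 8 for foreground components and 4 for holes, the
  standard dual pairing that avoids topological paradoxes.
* The large-area filter applies only to the ratiometric and phasor
  outputs, hole filling only to phasor, and the optional ROI intersection
  is skipped for a deep-learning method tag; the chain order follows the
  protocol's listing. ROC curves are swept after the first two steps only.

## Consensus and evaluation

Ground truth is per-pixel majority voting (default: at least 2 of 4
annotators), computed *before* the filter chain; the chain is then applied
with the "truth" tag. Sensitivity/specificity pool pixel counts across the
dataset (one confusion table per method, the convention that makes a
single reported pair meaningful for a 100-image study); per-image
averaging is available via a flag. AUC is a trapezoid over (1−specificity,
sensitivity) with (0,0) and (1,1) anchors. Dice of two empty masks is
defined as 1 (perfect agreement on absence). The ICC is the single-measure
two-way random-effects absolute-agreement form ICC(A,1) — each method
contributes one area per image — with the McGraw & Wong F-based 95% CI;
absolute agreement is used precisely because it penalizes systematic area
offsets. Bland–Altman differences are percent of the pair mean (the
denominator consistent with plotting the pair mean on the x-axis), with
limits of agreement mean ± 1.96·SD; zero-mean pairs are excluded with a
warning. Percent error for calibration is |(A_seg − A_gt)/A_gt|·100,
minimized per image; ties go to the smaller parameter (the more
conservative segmentation).

## Synthetic data: what it emulates and what it does not

The generator emulates the *optical contrast* of the stain pair, not its
histology. Defaults: 384×384 px at 0.5 µm/px (a desk-scale field that
still fits a 6000 µm² deposit with room to spare — the package's choice of
fixture scale), 3 deposits per image with areas log-uniform over
[5, 6000] µm² so the filter bounds are straddled, deposit color
(60, 60, 200) ± 12 per channel (ratio median ≈ 0.09, normalized phasor
≈ (0.44, 0)), background (220, 140, 170) ± 8 (ratio median ≈ 1.06, phasor
≈ (−0.02, 0.13)). Deposits are random star-convex outlines (low-order
Fourier radial perturbation of an ellipse, solved for the requested area)
with a 1-px anti-aliased rim, so boundary pixels are genuine color blends
and neither segmenter can be pixel-perfect. Shadow artifacts are grey
patches (115 ± 6 shared-intensity jitter, ± 2 chromatic) that sit at
ratio ≈ 1 and phasor ≈ origin: far from the deposit signature in both
feature spaces, they test that calibrated parameters reject achromatic
darkening. Annotators redraw each deposit with boundary dilation/erosion
of random integer radius ≤ 2 px and miss deposits < 50 µm² with
probability 0.1, which puts the inter-annotator area ICC in the > 0.9
regime reported for trained human raters.

Not modelled: staining batch variation, uneven illumination, tissue
texture, out-of-focus blur, touching/overlapping deposits, and non-deposit
blue contaminants. Passing tests therefore demonstrate correctness of the
algorithms and well-posedness of the calibration under the stated color
model — not segmentation accuracy on real slides.

## Numerical choices and degenerate inputs

* Zero-blue pixels: ratio sentinel 1e12 (never below any grid threshold).
* Zero-intensity pixels: normalized phasor (0, 0).
* Images with zero ground-truth area are excluded from calibration with a
  warning (their percent error is undefined).
* ICC with zero total variance raises (undefined); a perfect ICC of 1
  returns a collapsed CI.
* Sensitivity/specificity raise on empty positive/negative truth rather
  than returning NaN.
* Histogram edges are fixed at [−1, 1]; values exactly at +1 fall in the
  last bin (numpy closed right edge).
* All randomness flows through explicit `numpy.random.Generator` objects;
  dataset generation spawns per-image child seeds from one
  `SeedSequence`, so outputs are byte-identical for a given seed.

## Problem sizes

The bundled evaluation pipeline (tests and `scripts/acceptance.py`) uses
20 images of 384×384 px with 4 simulated annotators, a 101-point threshold
grid and a 40-point radius grid — the package's standard desk-scale study
configuration.

## Known limitations

* The bluest-bin search operates on the raw histogram; a smoothed or
  count-weighted variant would stabilize the gate centre but would change
  the declared criterion.
* The phasor radius grid is capped at 0.5; images whose gate centre is
  displaced far into the cluster tail can rail at the cap, which the mean
  across images dampens but does not eliminate.
* No white-balance or cross-microscope normalization is attempted; the
  ratio is applied to stored pixel values as-is.
* Whole-slide formats and tiling are out of scope; inputs are single
  calibrated TIFF/PNG fields of view.
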