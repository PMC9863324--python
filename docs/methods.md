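# Methods

`aortamech` quantifies the elastic behaviour of the ascending aorta from
time-resolved (cine) MR image sequences, and compares those in-vivo measures
with ex-vivo biaxial tensile properties of resected wall samples. This note
documents the models, the numerical choices behind them, and what the
synthetic phantom study does and does not demonstrate.

## In-vivo elastic properties

A cine acquisition images one axial slice at the level of the pulmonary
trunk over ~30 cardiac phases. From a binary segmentation of the ascending
aorta in every frame, two quantities are derived:

**Compliance** — the cross-sectional area swing over the cycle divided by
the pulse pressure recorded at the exam:

    C = (A_max − A_min) / (P_sys − P_dia)        [mm²/mmHg]

**Wall strain** — the outer-perimeter swing relative to its minimum:

    ε_wall = (P_max − P_min) / P_min             [dimensionless]

Areas are pixel counts scaled by the per-axis pixel spacing. Perimeters are
measured sub-pixel: the binary mask is smoothed with a Gaussian (σ = 1.5 px)
and the iso-0.5 level set is extracted by marching squares with linear
interpolation. Contouring the raw binary mask instead follows the pixel
staircase and overestimates smooth perimeters by ~6%, which would swamp a
9% perimeter swing; the smoothed level set reduces the error to ~0.2% for
vessel-sized masks (tiny masks that smooth below the iso level fall back to
the raw contour).

### Quadrant-local properties

The cross-section is divided about its center of gravity into four 90°
sectors, rotated by a configurable offset (default 60°) so the sectors align
with the medial, anterior, lateral and posterior walls. Conventions that the
literature leaves open and that are therefore explicit configuration here:

- Angles are measured counterclockwise from the +column axis in a y-up image
  frame; sectors are half-open `[start, start + 90°)`, so the four sector
  masks partition the lumen exactly.
- The counterclockwise label cycle starting at the offset is
  (lateral, anterior, medial, posterior); reports always print quadrants in
  the order medial, anterior, lateral, posterior. The anatomical mapping is
  a convention, not a measurement — results are label-permutation complete.
- The centroid is recomputed per frame by default (the vessel moves);
  `fixed_centroid=True` pins the first frame's centroid for sensitivity
  analysis.
- Per-quadrant compliance and strain use each quadrant's own extremal
  frames, i.e. the global formulas applied verbatim to the quadrant curves.

Quadrant outer-arc lengths subdivide contour segments exactly at the
sector-boundary angles (linear interpolation of the vertex angles). Without
this, the cut position is quantised by the ~1 px contour vertex spacing,
which alone perturbs a quadrant's arc swing by tens of percent; with it the
four arcs sum to the total perimeter exactly and quadrant strains of a
uniformly pulsating phantom agree within ~1.5%.

## Segmentation

A plain U-Net (the variant selected for this task) with instance
normalisation after every convolution and before every ReLU; channels double
per level; 2×2 max-pooling down, nearest-neighbour upsampling + convolution
up; a 1×1 convolution and sigmoid produce the probability map. A
`residual_blocks` toggle turns every level into a residual block
(Residual-U-Net). Attention/recurrent/nested variants are out of scope.

Training follows the protocol: Adam, initial learning rate 1e-3, soft Dice
loss (smoothing ε = 1e-6, which makes it equal to 1 − Dice coefficient on
hard masks and stable on empty ones), learning rate ×0.1 after 5 epochs
without validation improvement, early stopping with patience 16, at most 200
epochs, and 5-fold cross-validation grouped at the exam level — all frames
of an exam stay in one fold. After cross-validation the returned model is
retrained on all training exams. A single fit with an explicit validation
set (`cross_validate=False`) is available when no fold-wise estimate is
needed; the desk-scale evaluations use it to keep one training run instead
of six. Values the protocol leaves unstated and that are therefore
configuration defaults, not reproductions: batch size 8 (the scaled-down
evaluations use 2, which converges faster per image seen), Adam betas
(0.9, 0.999), augmentation ranges (rotation ±15°, flips p = 0.5, scale
0.9–1.1, translation ±5%).

Inference thresholds the sigmoid map at 0.5 and keeps the largest connected
component — there is a single target structure per frame. Preprocessing is
min-max normalisation to [0, 1], optional percentile histogram stretching
(default 1–99, robust to bright flow artifacts), and center-crop-padding to
the model's input size; constant frames normalise to zeros.

The network engine is a small numpy implementation written for this package
(3×3 convolutions as nine offset matmuls, instance norm, ReLU, pooling,
upsampling, Adam, manual backprop, float32). It is exact — parameter
gradients are verified against finite differences in the test suite — and
CPU-sized: ~0.3 s per 128×128 image forward+backward at base width 16.

### Scale profiles

The full-scale configuration is 256×256 inputs with base width 32. The desk
profile used by the automated evaluations is 128×128 inputs, base width 16,
depth 3 (16×16 bottleneck): a cohort of 40 phantom exams × 4 frames trains
in ~3 minutes on one CPU and reaches held-out Dice ≥ 0.99 on full-cycle
phantom exams, with end-to-end compliance within ~2% of analytic truth.

## The phantom study

Patient data is not redistributable, so every stage is validated on a
synthetic phantom with exact ground truth. One exam is a 256×256, 30-frame
sequence (1.17 mm/px default, inside the 1.09–1.25 mm/px acquisition range)
containing a bright quasi-elliptical lumen over a darker background. The
default geometry is a pre-surgical aneurysm: semi-axes 28 × 24 mm
(a ~56 mm vessel), tilted 25° and a few pixels off-center. Semi-axes follow
a single-peaked waveform — raised-cosine systolic rise (peak at 35% of the
cycle) and slower raised-cosine decay — sampled so that frame 0 is exact
diastole and the peak lands on a frame, making the sampled extrema equal the
analytic ones. The pulsation amplitude (default 0.09) is chosen so the wall
strain matches the ~0.07–0.10 range reported for aneurysmal quadrant
strains; compliance then follows from the (large) phantom geometry and is
higher than typical stiff-aneurysm values — the phantom reproduces shape
dynamics and measurement conditions, not one patient's pressure-area
physiology.

Masks are exact rasterisations of the analytic ellipse (pixel centers
inside). Truth carries per-frame areas (πab), perimeters (Ramanujan's second
approximation, error ≈ 1e-10 at these aspect ratios), per-quadrant elliptic
sector areas (closed form via the eccentric-anomaly substitution) and arcs
(dense polyline integration), with sector bounds expressed in the tilted
ellipse frame. Noise, flow-artifact dropout patches, a ghosting streak and
an optional abutting neighbour vessel corrupt only the intensities, never
the masks or the truth. `sample_cohort` draws per-exam geometry — pixel
spacing U(1.09, 1.25), semi-axes ±10%, tilt U(0°, 180°), center offset
±8 px, pulsation U(0.06, 0.12) — giving the between-subject variance that
training and agreement statistics need. The tilt and off-center defaults
also matter numerically: an axis-aligned, grid-centered ellipse resonates
with the pixel lattice and can push the rasterisation error of the area
*swing* (a difference of two large numbers) past 2%, while tilted off-grid
geometry keeps compliance and strain recovery near 1%.

What passing phantom tests does **not** show: robustness to real MR
contrast, through-plane motion, expert-contour variability, non-elliptical
aneurysm shapes, or wall-to-wall strain heterogeneity (the phantom pulsates
uniformly, so true quadrant strains are all equal — which is exactly what
makes it a calibration target).

## Ex-vivo tensile analysis

Square wall samples (15 × 15 mm, default thickness 2 mm) are stretched after
preconditioning; the machine records force vs displacement per axis (two
axes analysed as two records). Engineering strain ε = (l − l0)/l0 and stress
σ = F/A0 with A0 = thickness × l0, so MPa = N/mm². Duplicate-strain samples
(dwell points) are averaged. A helper trims leading preconditioning cycles
by locating the last return to near-zero force.

Young's modulus along the curve is the **tangent** modulus dσ/dε — central
finite differences after moving-average smoothing of σ (default window 11
samples). The literal secant ratio σ/ε is available as an option since the
printed formula is a plain ratio; the prose describes a first derivative, so
tangent is primary. Two summaries:

- `E_max`: maximum of the modulus curve, attained on the stiff
  collagen-dominated branch. Note the estimator caveat: the maximum of a
  noisy derivative is biased upward; heavier smoothing trades that bias for
  blur. The acceptance checks use noiseless curves (exact) and the mean
  modulus for noisy ones (unbiased).
- `E_phys`: mean modulus over the physiological stress window
  [σ(P_dia), σ(P_sys)], with pressure mapped to wall stress by thin-wall
  Laplace hoop stress σ(P) = P·r/t (1 mmHg = 1.33322e-4 MPa). The mapping
  to ex-vivo stress is not fully specified in the source protocols, so the
  geometry (radius, wall thickness) is an explicit argument and the mapping
  is documented rather than implied. E_phys ≤ E_max for any curve.

The simulator inverts these relations from a piecewise-linear σ(ε) with
configurable segment moduli (default 0.3 MPa then 1.2 MPa, in the reported
range for aneurysmal tissue), plus seeded Gaussian stress noise.

## Agreement statistics

Pearson correlation with the two-sided t-transform p-value (Spearman as a
flag), Bland-Altman mean difference ± SD with 1.96-SD limits of agreement,
and per-quadrant cohort summaries. Sample statistics use the n−1
denominator throughout. The Bland-Altman convention is predicted − reference,
so positive mean differences read as overestimation by the automatic method.

## Degenerate inputs and tie-breaks

- Constant frames normalise to all-zeros (no contrast to preserve).
- Percentile stretch with a collapsed window falls back to min-max.
- Center-crop-pad sends the extra pixel to the trailing side on odd
  differences.
- Both-empty mask pairs score Dice = IoU = 1; empty-denominator precision/
  recall is 1 when the counterpart is also empty, else 0. Hausdorff on an
  empty mask is an error (undefined), and frames where it is undefined enter
  aggregates as NaN.
- Sector-boundary pixels belong to exactly one quadrant (half-open sectors).
- Max-pool gradient ties propagate to all maxima (ties are measure-zero for
  continuous activations).

## Known limitations

- 2D single-slice analysis; no 3D geometry, no pulse-wave velocity.
- The numpy engine is CPU-only and unbatched across devices; full-scale
  (256 px, base 32) training is possible but slow — the package is sized for
  method validation, not large-cohort training runs.
- Hausdorff is the true maximum (HD100); HD95 is not implemented.
- The anatomical quadrant labelling is a configurable convention; only the
  partition geometry is testable.
- `E_max` on noisy records inherits derivative-noise bias (see above).
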