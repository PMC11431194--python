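# Methods

## Measurement model

The pipeline works in 0-based image coordinates: `x` increases rightward
(columns), `y` downward (rows), pixel centers at integer coordinates.
Superior anatomy therefore has smaller `y`. Four landmarks are defined on
the per-class masks of an AP shoulder radiograph:

- **G, I** — superior and inferior poles of the glenoid rim: the boundary
  pixels of minimal / maximal row, with ties broken toward anatomical
  lateral. The glenoid is near-vertical in an AP view, so the extremal-row
  rule coincides with intersecting the rim with a vertical line while
  being parameter-free and reproducible.
- **A** — the lateral-most acromion boundary pixel, ties broken inferior
  (the clinically relevant inferolateral acromial corner).
- **H** — the lateral-most humeral boundary pixel, ties broken superior
  (the lateral margin of the head).

Boundary pixels are foreground pixels with at least one 4-neighbor that is
background or off-image; 4-connectivity gives thinner, deterministic edges
than 8-connectivity. Only the largest 4-connected component of each class
is used (instance segmenters occasionally spill speckle pixels across
classes; one bone per class is the anatomical ground truth), and each
region must retain at least `min_region_pixels` (default 10) pixels — a
guard against speckle-only masks.

Laterality (whether anatomical lateral is +x or −x) is inferred from the
sign of the humerus−glenoid centroid difference in x: the humeral head is
lateral to the glenoid in an AP view. Differences under 1 px are rejected
as ambiguous rather than guessed. Vertical orientation is inferred
analogously from the acromion−humerus centroid difference in y (the
acromion sits above the humeral head); upside-down inputs are flipped
before extraction so the superior-up landmark rules apply, which is what
makes the measurements invariant under the y-symmetry and 180°-rotation
augmentations.

From the landmark set:

- `CSA = ∠(I→G, I→A)` at the inferior glenoid pole, in degrees.
- `AI = d⊥(A, GI) / d⊥(H, GI)` — perpendicular distances to the glenoid
  line. A point-to-point reading of "distance GA over distance GH" would
  leave the glenoid reference point undefined and break scale consistency;
  the glenoid-plane perpendicular construction is the clinical one and is
  what is implemented.
- `LAA = ∠(V→A, V→H)` with `V = (G+I)/2`. The glenoid reference point for
  this angle is otherwise under-determined; the midpoint is deterministic
  and symmetric in G and I. Note this angle differs from the classical
  undersurface-based lateral acromion angle; the two should not be
  compared numerically.

Angles are computed from direction vectors via `atan2(|cross|, dot)`,
giving the non-negative ray angle in [0, 180]°. This avoids the
singularities of the two-slope formula `tan⁻¹|(m₁−m₂)/(1+m₁m₂)|` at
vertical lines (the glenoid line is near-vertical by construction) and at
perpendicular slope pairs; the slope formula is retained as an independent
cross-check (`geometry.angle_between_slopes`) and the two agree to well
below 1e-9° wherever both are defined. Points closer than 1e-9 px are
treated as coincident and rejected as degenerate geometry.

## Risk bands

Values are classified into the conventional clinical categories:
CSA `<30 | [30, 35) | ≥35`, LAA `<45 | [45, 55] | >55`,
AI `<0.7 | [0.7, 1) | ≥1`. The LAA middle band is closed at both ends
while the CSA and AI middle bands are half-open; the boundary conventions
are preserved exactly, and each partition covers every positive value
exactly once.

## Agreement statistics

Repeated measurements are analyzed with the one-way random-effects
intraclass correlation for single ratings,
`ICC(1,1) = (MSB − MSW) / (MSB + (k−1) MSW)`, from the one-way ANOVA
decomposition over subjects (n subjects × k repeats, no missing cells).
The confidence interval is the exact two-sided F-based (Shrout–Fleiss)
interval: with `F = MSB/MSW` on `(n−1, n(k−1))` degrees of freedom, the
bounds are `(F/F_u − 1)/(F/F_u + k − 1)` and `(F/F_l − 1)/(F/F_l + k − 1)`.
The implementation is validated against pingouin's ICC1 in the test
suite. Reliability labels: ≥0.9 excellent, [0.75, 0.9) good, [0.5, 0.75)
moderate, <0.5 poor (the poor band absorbs the whole lower tail so the
labels partition the line).

RMSE is the root of the mean squared residual between paired sequences —
the standard definition matching the name, not a root of averaged raw
residuals. Summary statistics use the sample (n−1) standard deviation.
Segmentation overlap uses Dice `2|A∩B|/(|A|+|B|)` and Jaccard
`|A∩B|/|A∪B|`; both are undefined (rejected) for two empty masks.

Reference losses for validating a detection backend: binary cross-entropy
`−W[y log x + (1−y) log(1−x)]` with predictions clamped to
`[1e−7, 1−1e−7]` so perfect-confidence mistakes are finite (≈16.12), and
complete-IoU `1 − IoU + ρ²/c² + αv` with aspect term
`v = (4/π²)(atan(w_g/h_g) − atan(w/h))²` and `α = v/((1−IoU)+v)`; the 0/0
case at `IoU = 1, v = 0` is defined as 0, where the loss is already 0.

## Phantom generator

The generator is the package's ground-truth source: it inverts the three
measurement constructions in closed form. With the glenoid segment of
length `L` placed vertically (G above I) and lateral = +x:

1. A is placed on the ray leaving I at exactly the CSA target from I→G,
   at lateral offset `d_A = 0.7 L`. The 0.7 ratio is the generator's one
   free parameter — a lateral acromial extension of 70 % of the glenoid
   height, in the anatomically plausible range.
2. H is placed at lateral offset `d_H = d_A / AI`, with its row chosen so
   the angle at `V = (G+I)/2` between V→A and V→H equals the LAA target:
   `θ_H = θ_A + LAA` where `θ_A` is the inclination of V→A. If
   `cos θ_H ≤ 0` the humeral ray would not point lateral and the triple is
   rejected as infeasible (never clipped).

Forward measurement of these continuous landmarks reproduces the targets
to machine precision (≈1e−14 observed). The landmarks are then shifted by
an integer offset onto a canvas with a margin proportional to `L`
(measurements are translation-invariant), and rasterized as three
disjoint regions: a glenoid strip whose top/bottom boundary rows land on
G and I, an acromion slab (with a random medial taper) whose lateral-most,
tie-inferior boundary pixel lands on A, and a humeral disk whose
lateral-most, tie-superior pixel lands on H. Shape details — strip width
(~4–8 px at L = 120), slab thickness (~8–16 px) and length, disk radius
(~12–19 px) — are seeded-random within ranges proportional to `L`, so
phantoms vary without moving the extremal landmarks. Overlap after
rasterization raises a rendering error rather than silently merging
regions.

Because each extremal boundary pixel is the rounded continuous landmark,
raster-pipeline recovery error is bounded by the ≤0.5 px per-coordinate
quantization over lever arms of order `L`: at `L = 120` px the observed
median absolute errors over a 5×5×5 target grid (CSA 25–45°, AI 0.5–1.1,
LAA 40–70°) are ≈0.02° (CSA), ≈0.09° (LAA) and ≈0.001 (AI), comfortably
inside the 1° / 0.03 acceptance bands. The default target box for random
phantoms is that same grid range — inside clinically observed value ranges
and jointly feasible everywhere for the closed-form construction.

What the phantoms do **not** emulate: real radiographic texture, soft
tissue, projection obliquity, or segmentation error with realistic spatial
structure. A boundary erosion/dilation corruption option exists for
robustness tests but is not calibrated to any segmenter's error
statistics. Passing the phantom battery therefore demonstrates the
correctness of the geometry and post-processing, not the accuracy of any
upstream segmentation model on clinical images.

## Dataset bookkeeping

The default augmentation scheme applies exactly four transforms per item —
identity, x-symmetry, y-symmetry and 180° rotation — expanding 140 items
to 560. The four axis-aligned symmetries are closed under composition,
introduce no interpolation artifacts, and keep masks on-grid; arbitrary-
angle rotation is deliberately excluded from the count-critical default.
The identity transform is included so the expansion factor is exactly 4.
Train/test splitting is a seeded permutation partition (e.g. 217 ids →
140 train + 77 test), disjoint and exhaustive by construction.

## File formats and numerics

Label maps are single-channel 8-bit PNGs with 0 = background, 1 =
acromion, 2 = glenoid, 3 = humerus; unknown values are rejected, never
coerced. Polygon text files follow the `class_id x1 y1 ...` normalized
dialect with class order acromion/glenoid/humerus; polygons are filled by
even-odd pixel-center containment (shapely), and the writer traces
half-level contours (scikit-image), so a write/read round trip reproduces
masks to DSC ≥ 0.99 rather than bit-exactly. Image↔mask association is by
filename stem; collisions are errors. Reports are written with fixed
column orders and 6-decimal floats so byte-level diffs are meaningful.

## Problem sizes

The test suite and the acceptance script use phantoms at glenoid length
120 px (canvas ≈ 230–330 px square), a 5×5×5 target grid for recovery
statistics, 10,000 random triples for the angle-formula comparison, and
1,000 random mask pairs for the overlap-metric identity — sizes at which
every reported statistic is already stable at the precision quoted above.
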