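# Methods

## Measurement model

A polyp border is modelled as a closed, near-planar curve in 3D. Two
calibrated views with known camera poses (from an EM tracking sensor plus
a fixed hand–eye transform) determine the border in real scale: matched
border points are back-projected to rays in the tracker frame and
triangulated, a plane is fitted to the resulting point cloud, and an
ellipse is fitted in that plane. The ellipse's full major axis is the
clinically reported "longest length"; the Euclidean distance from the
ellipse centre to a tracked landmark (e.g. the oesophago-gastric junction)
is the reported location. The ellipse is a deliberate low-order model:
polyp borders are irregular, but guidelines key on a single longest
length, and a conic absorbs the dominant elongation while averaging
segmentation noise.

Assumptions: the polyp is stationary between the frames of a pair (pairs
that disagree are culled statistically, see below); the border is close to
planar (out-of-plane structure inflates the fit error, which is monitored
per pair); the camera is calibrated and the hand–eye transform known
(both are config inputs; calibration itself is out of scope).

### Conventions

Right-handed camera frame, optical axis +z, image x right / y down,
0-based pixel coordinates with (0, 0) the top-left pixel centre.
Quaternions are scalar-first (w, x, y, z) and rotate frame coordinates
into tracker coordinates; the pose log stores the *sensor* pose and the
rig's hand–eye (sensor → camera, identity by default) completes the
camera pose. All lengths are mm, all interface angles degrees.
Distortion is Brown–Conrady (k1, k2, p1, p2, k3); back-projection inverts
it by fixed-point iteration (cap 50 iterations, tolerance 1e-12).

### Triangulation

Midpoint of the common perpendicular between the two viewing rays, chosen
over a linear DLT because it matches the two-ray formulation, is exact for
noiseless fixtures, and yields an interpretable per-point residual — the
length of the perpendicular segment in mm. Rays with sine of the
inter-ray angle below 1e-6 are rejected as degenerate. Correspondences
with residual above `residual_cap_mm` (default 2 mm) are treated as
mismatches and dropped; at least 6 points must survive for a conic to be
identifiable.

### Ellipse fitting

Plane by PCA (centroid + two leading principal directions; collinearity
rejected when the second singular value vanishes), then the
ellipse-specific direct least-squares conic fit (Halir–Flusser
formulation, numerically stable variant of the Fitzgibbon method) on the
in-plane coordinates. Deterministic and closed-form; a hyperbolic or
parabolic solution raises an error rather than returning a size. The
reported `rms_fit_error_mm` is the RMS in-plane radial distance of the
points to the fitted ellipse, ~0 for exact data, and doubles as a
model-validation statistic (below). Axis lengths are sorted explicitly
because the overall sign of a fitted conic is arbitrary.

## Shape-context correspondence

Each of the `n_samples = 100` arc-length-resampled border points gets a
log-polar histogram (5 radial × 12 angular bins; radial range 1/8–2× the
shape's mean pairwise distance, log-spaced; out-of-range points dropped)
of the other points' relative positions. Radius normalisation by the mean
pairwise distance gives scale and translation invariance. Angles are kept
in the image frame — no rotation normalisation — because valid view pairs
are constrained below 30° relative rotation and absolute orientation is
the only cue that disambiguates the two ends of a near-symmetric border.
Histograms are compared by the χ² distance on normalised counts and the
assignment is solved exactly (Hungarian algorithm); no dummy outlier
points are added since both contours come from the same physical border.
Thin-plate-spline warping and iterated registration are intentionally
absent: a single matching pass feeds the geometric reconstruction, which
has its own outlier defenses.

### Failure mode: phantom curves, and the consistency screens

Along a smooth closed border, neighbouring shape contexts are nearly
identical, so the optimal assignment can lock onto a *coherent cyclic
slip* — every match offset by the same small arc length. Slipped
correspondences still triangulate with small residuals (the two viewing
cones intersect along a smooth curve), but the reconstructed curve is the
cone intersection, not the border: wrong size, nearly correct centre, and
generally not an ellipse. Because the centre is preserved, the
centre-based quartile rule alone cannot catch it. Two per-pair screens
run before aggregation:

1. **Fit-quality gate** — drop pairs with
   `rms_fit_error_mm > max(0.5 mm, 3 × median over pairs)`. On simulated
   study conditions good pairs sit at ~0.1–0.4 mm and phantom pairs at
   ~1–4 mm; the adaptive term keeps genuinely wavy (non-planar) borders,
   which raise every pair's fit error together, from being culled.
2. **Size-consistency fence** — drop pairs whose size is outside
   `median ± max(3 × MAD, 0.5 mm)` of the per-pair sizes. MAD rather than
   quartiles because phantom pairs can approach half the set, where the
   upper quartile is already corrupted.

If a screen would drop every pair it is skipped (single best pair kept).
Screened pairs are reported with the rule that removed them.

## Aggregation

Pairs surviving the screens enter the quartile rule: the component-wise
median centre is computed, each pair's centre distance to it taken, and
pairs beyond `Q3 + 1.5·IQR` flagged as outliers (Tukey fence, `iqr_k`
configurable) — a stationary polyp must yield the same centre from every
pair, so a displaced centre indicates polyp movement between captures.
Final size and location are arithmetic means over the non-flagged pairs;
if all would be flagged the single pair nearest the median centre is
kept.

## Motion-quality gate

Triangulation conditioning and tracking-error accumulation motivate
per-pair capture rules, evaluated exhaustively (never short-circuited) so
operator feedback names every violation: relative translation > 30 mm
(`large_translation`), relative rotation > 30° (`large_rotation`),
translation < 3 mm (`minimal_movement`), and translation within 15° of
the mean optical axis (`forward_backward` — rays nearly collinear with
the baseline triangulate poorly). The 30/30/3 bounds are strict
inequalities (exactly 30 mm or 3 mm passes); the 15° forward-angle
threshold is this package's quantification of "pure forward–backward"
and is configurable. The mean *camera* optical axis is used.

## Synthetic scenes

The simulator generates what a bench validation would provide:

- **Borders**: planar ellipses with longest length 5–20 mm (the common
  clinical range), optional smooth out-of-plane waviness (amplitude in mm,
  3rd-harmonic displacement with seeded phase) standing in for asymmetric,
  non-rigid polyps. The stored ground truth is the generating major axis.
- **Poses**: cameras on a spherical cap facing the border at ~60 mm
  working distance with lateral spread tuned so *every* pose pair
  satisfies the motion recommendations (verified by the gate itself,
  rejection-sampled with a retry budget); a shared up-vector with small
  roll jitter keeps relative rotations dominated by the viewing-direction
  change.
- **Rendering**: masks are the filled projected polygon; contours are the
  exact projected border points plus isotropic Gaussian pixel jitter;
  poses are perturbed by Gaussian position noise and axis-angle rotation
  noise. Defaults σ = 0.3 mm / 0.3° / 0.5 px are plausible EM-tracker and
  segmentation magnitudes, stated as configuration rather than estimates
  of a specific device. Everything is deterministic under the scene seed.

Default camera: 640×640 px, fx = fy = 330 (≈88° horizontal FOV,
endoscope-like), zero distortion, identity hand–eye; all configurable.

What the simulator does *not* emulate — photorealistic appearance,
segmentation-model error structure (masks are geometrically exact up to
rasterisation), tissue deformation during a capture session, tracker
noise spectra or field distortion near metal. Passing tests therefore
demonstrate the geometry, matching and statistics of the method under
controlled noise, not clinical performance.

### Accuracy cohort

`run_accuracy_cohort` (used by `scripts/acceptance.py` and the acceptance
tests) simulates 30 polyps, major axes uniform in 5–20 mm, aspect ratio
uniform in 0.55–0.9, waviness 0, five views each, landmark 150–250 mm
away, and measures each with the full shape-context pipeline on the noisy
contours and poses. 30 polyps × C(5,2) = 10 pairs runs in well under a
minute on one CPU. Observed size RMSE is ~0.3–0.5 mm and location RMSE
~0.5–0.8 mm across seeds, inside the ≤1 mm / ≤3 mm accuracy envelope the
capture recommendations are designed to guarantee.

A noteworthy non-monotonicity: with *zero* pixel noise the matcher's
cyclic slip on a perfectly smooth border is fully systematic, so size
error at σ_px = 0 can exceed that at σ_px = 0.5 px — a little noise
dithers the descriptor ties. The monotone noise-degradation property
therefore holds in exact-correspondence mode (pure geometry), and the
property test runs that mode.

## Agreement statistics

- **ICC**: single-measure absolute-agreement intraclass correlation from
  the two-way mean squares,
  `(MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`, with the
  standard F-based confidence bounds and an F-test of ICC = 0 on
  (n−1, (n−1)(k−1)) df. Single-measure because each session yields one
  measurement per polyp.
- **Bland–Altman**: differences in units or percent of the pairwise mean;
  limits `d ± 1.96s` (1.96 chosen over the rounded 2.0; `loa_factor=2.0`
  available), t-based CI for the mean difference, Shapiro–Wilk normality
  p-value attached as advisory — the analysis always computes rather than
  refusing on non-normal differences. Zero-variance differences are
  flagged degenerate with collapsed limits.
- **Error summaries**: RMSD, median and IQR of absolute differences,
  mean ± SD absolute percentage relative to the reference series.
- **Sample size**: Fisher-z formula
  `n = ((z_{1−α/2} + z_{power}) / atanh(r))² + 3`, inflated by the safety
  margin and rounded up once at the end (a single ceiling after inflation;
  rounding at both stages would overshoot the intended conservative
  count). Defaults r = 0.7, α = 0.05, power = 0.8, +10% give 15.

## Known limitations

- Location is straight-line Euclidean distance in tracker coordinates,
  not along-lumen path length — the tracker yields point positions only.
- The ellipse fit is algebraic; with heavy point noise algebraic conic
  fits are biased toward smaller ellipses. At the noise levels of the
  intended capture protocol the bias is far below the clinical decision
  thresholds.
- Single-pass matching cannot recover from a border whose two ends are
  genuinely indistinguishable in the image frame *and* whose pairs all
  slip identically; the screens reduce but cannot eliminate this.
- No volume or full-surface reconstruction; the longest length is the
  clinically mandated quantity.
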