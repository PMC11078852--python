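# endopolyp

Quantitative measurement of polyp **size** (longest length, mm) and
**location** (distance to an anatomical landmark, mm) from pairs of
monocular endoscopic images whose camera poses are known from an
electromagnetic (EM) tracking sensor.

Visual size estimation during endoscopy is unreliable — the apparent size
of a lesion on the monitor depends on the unknown camera–tissue distance —
yet resection technique and surveillance intervals hinge on thresholds like
5, 10 or 20 mm. If the camera pose at each frame is known in a fixed
tracker frame, two views of the same polyp border determine its real-scale
3D geometry with no scale ambiguity.

## Method

Given segmented polyp masks and tracked poses for `n ≥ 2` frames:

1. **Border extraction** — masks are cleaned (morphological opening,
   small-component removal, hole filling, optional Chan–Vese active-contour
   refinement) and the outer border is traced at sub-pixel resolution and
   resampled uniformly by arc length.
2. **Shape-context correspondence** — endoscopic mucosa is texture-poor,
   so points are matched on *shape*: each border point `p_i` gets a
   log-polar histogram (5 radial × 12 angular bins) of the relative
   positions of all other border points, with radii normalised by the mean
   pairwise distance. Histograms are compared with the χ² distance
   `C(p,q) = ½ Σ_k (h_p(k) − h_q(k))² / (h_p(k) + h_q(k))` and a globally
   optimal one-to-one assignment is solved with the Hungarian algorithm.
3. **Triangulation** — each correspondence is back-projected from both
   views and triangulated as the midpoint of the common perpendicular
   between the two rays; the perpendicular's length is the residual (mm)
   and mismatches above a 2 mm cap are dropped.
4. **Ellipse fit** — a plane is fitted to the 3D border (PCA), points are
   projected into it and an ellipse-constrained direct least-squares conic
   fit is solved. The fitted **major axis is the reported polyp size**; the
   distance from the ellipse centre to the landmark (e.g. the
   oesophago-gastric junction) is the reported location.
5. **Multi-pair aggregation** — all C(n,2) frame pairs that satisfy the
   capture recommendations (relative translation in (3, 30) mm, rotation
   < 30°, not purely forward–backward) are measured independently; pairs
   whose centre is a quartile outlier (Tukey fence) are excluded and the
   remaining estimates averaged.

The package also ships a ground-truthed scene simulator (synthetic polyp
borders, endoscope-like pose sets, rendered masks with configurable pose
and pixel noise) and the reliability statistics used to validate such a
system: two-way mixed-effects absolute-agreement ICC, Bland–Altman limits
of agreement `d ± 1.96s` (unit and percent), RMSD/median-absolute-error
summaries, and the Fisher-z correlation-based sample-size calculation.

## Worked example

Simulate a 12 mm polyp seen from five tracked views, then measure it:

```sh
endopolyp simulate --out scene/ --seed 1 --major-mm 12 --minor-mm 7
endopolyp measure --masks scene/masks --poses scene/poses.csv \
    --rig scene/rig.yaml --landmark scene/landmark.json --out report.json
```

which prints

```
wrote synthetic scene (5 views) to scene
final size: 12.01 mm | location: 191.90 mm | pairs used: 7/10
```

`report.json` holds the final block plus a per-pair table (size, centre,
landmark distance, triangulation residuals, motion-quality scalars,
outlier flags). Here the fitted longest length of 12.01 mm recovers the
simulated 12 mm ground truth to within 0.01 mm and the landmark distance
of 191.90 mm is within 0.5 mm of the true 192.33 mm (`scene/truth.json`);
all 10 view pairs passed the motion gate and 7 survived the consistency
screens that guard against failed correspondences.

Test–retest agreement of repeated measurements:

```sh
endopolyp stats --input measurements.csv --out stats.json   # polyp_id,test,retest[,reference]
```

From the library, the same pipeline is three calls:

```python
from endopolyp import MeasureOptions, measure_polyp
from endopolyp.simulate import simulate_scene, render_views

scene = simulate_scene(major_mm=12, minor_mm=7, seed=1)
views = render_views(scene)
result = measure_polyp(list(zip(views.masks, views.noisy_poses)),
                       scene.rig, scene.landmark, MeasureOptions())
print(result.final_size_mm, result.final_location_mm)
```

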