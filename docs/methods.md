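# Methods

## Model and assumptions

The package estimates the tilt of a cabbage's main axis from two binary
instance masks (head, root) in one image frame. The core assumption is the
anti-gravity stem-seeking principle: the root grows against gravity, so the
head–root junction — invisible because the outer leaves wrap it — lies on the
upward continuation of the visible root trajectory. The pipeline encodes that
continuation as a quadratic Bézier curve through three keypoints:

* **P₀**, the geometric-moment centroid of the visible root. Moments are
  computed over pixel centers with unit weight; masks are binary
  post-segmentation rasters, so intensity weighting would be meaningless.
* **P₁**, the breakpoint where the occluding leaves truncate the root mask:
  the midpoint of the topmost foreground row, snapped to the nearest root
  contour point. P₁ is the *control* point of the quadratic — the curve bends
  toward it without interpolating it, which makes the prediction tolerant of
  the breakpoint's pixel-level jitter.
* **P₂**, the head centroid (an alternative `axis_top="top_midpoint"` mode
  anchors the axis at the midpoint of the head's top row instead; the
  centroid is the default because it is the more robust statistic of the two
  and matches the procedural description of the source method).

The predicted junction P₃ is the first curve sample (walking from the root
end, t = 0) whose nearest pixel lies in the head mask; pixels where head and
root masks overlap count as head, deterministically. The posture angle θ is
the unsigned deviation of the axis P₂P₃ from the vertical, in [0°, 90°], and
the posture rule is boundary-inclusive: θ ≤ β ⇒ VERTICAL, else TILTED.

A note on the angle convention: the classical slope form
θ = |tan⁻¹(Δy/Δx)| measures against the *horizontal*, yet the decision rule
"θ ≤ β means still vertical" only makes sense for a deviation from the
*vertical*. The implementation therefore defaults to deviation-from-vertical
(`atan2(|Δx|, |Δy|)`), and exposes the literal slope form via
`angle_reference="horizontal"` for anyone who wants the printed formula; the
two are complementary (they sum to 90°).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `beta_deg` | 10° | cutting threshold; tolerable axis deviation. No canonical value exists for harvester hardware in general, so it is always user-configurable. |
| `n_samples` | 200 | t-grid size for the curve/head intersection; sub-pixel spacing for frames up to ~1080 px. |
| `angle_reference` | `vertical` | see above. |
| `axis_top` | `head_centroid` | axis anchor point. |
| `snap_breakpoint` | `True` | snap the raw row-midpoint onto the root contour via the KD-tree before using it as P₁. |

The KD-tree is built from scratch (median split, alternating dimensions,
lower median on even counts, ties to the left) because exactness is part of
its contract: queries compare squared distances and break distance ties
lexicographically on (x, y), so P₁ selection is reproducible bit for bit.
Pruning visits the far half-space whenever its boundary distance *equals*
the current best — necessary for correct tie-breaking, and still sub-linear
in practice.

## Synthetic scenes

The generator emulates what an instance segmenter hands the pipeline, with
exact ground truth (true axis angle, true junction, pre-occlusion root):

* **Head**: a filled ellipse, semi-axes (a, b), rotated so that the b-axis
  lies along the stem direction; the junction is the boundary point at the
  end of that axis.
* **Root**: disks of radius `root_width/2` stamped along a quadratic Bézier
  leaving the junction in the stem direction, with the mid control point
  offset perpendicular by `0.25 * root_curvature * root_length` (sign chosen
  per scene by the seeded generator). The three field presets are
  curving (curvature 0.6, length 40 px), smallish (0.2, 25 px) and
  straight (0.0, 70 px).
* **Occlusion**: outer leaves droop under gravity, so the occlusion edge is
  modeled as a *horizontal leaf line* placed at the image height of the
  curve point whose arclength from the junction equals
  `occlusion_frac × root length`; all root pixels above the line are hidden.
  An iso-arclength (perpendicular-to-stem) cut was considered and rejected:
  its topmost image row degenerates to the cut's uphill corner for any
  tilted stem, which injects a ~w/2 lateral bias into the breakpoint that no
  resampling can remove and which misrepresents how leaf occlusion looks in
  gravity-aligned photographs.
* **Noise**: a seeded fraction of contour pixels is deleted (subtractive
  only), emulating ragged segmentation edges while preserving the
  visible ⊆ full containment invariant.
* The root mask is *not* carved out of the head mask: real instance masks
  overlap slightly at the attachment, scenes tolerate ≤ 5 % overlap, and
  subtracting the tilted ellipse was found to bite off the downhill half of
  the root's top row, biasing the breakpoint by ~0.8° on average.

Default scene statistics (frame 720×1080 matching the stated camera
resolution; head semi-axes U(80, 110) × U(65, 90) px; root width
U(10, 16) px; angles U(−40°, 40°); occlusion U(0, 0.4); noise U(0, 0.05))
are chosen once as plausible for close-range field imagery. Per-scene seeds
derive from the batch seed and scene index only (counter-based
`SeedSequence`), so batches are reproducible independently of generation
order.

The **rotate** augmentation deserves a note: rotating the *plant* does not
rotate *gravity*. When ground truth (the full root) is available, the op
rigid-rotates head and full root about the head centroid and then re-applies
a horizontal leaf line hiding the same area fraction as before. Without
ground truth it falls back to a plain rigid rotation of the visible masks —
correct for the masks, but the rotated occlusion edge then carries the
corner artifact described above. Mirror flips the ground-truth angle's sign;
a vertical flip inverts the scene (flagged in metadata) and leaves the
unsigned tilt unchanged. Brightness is a logged no-op on pure masks.

## What the synthetic tests do and do not show

Passing the synthetic suite shows the *mechanism* works: the Bézier
extrapolation recovers the hidden junction to sub-degree mean error where
estimators that read the visible root directly (minimum-area-rectangle
orientation; skeleton line fit) degrade with occlusion, curvature and edge
noise — and the three agree on clean straight stems. It does not certify
accuracy on real imagery: real masks have segmentation errors correlated
with scene content, leaf boundaries are ragged rather than straight,
multiple plants may appear per frame, and real root shapes are not disks
along a quadratic. Absolute error numbers here (≈0.5° MAE) are therefore
better than the ~1.4° reported for field imagery by comparable pipelines,
as expected for idealized geometry.

## Numerical choices

* De Casteljau is the production curve evaluator (numerically stable,
  cheap); the Bernstein form is kept as an independent formulation and the
  two are property-tested to agree within 1e-9 across degrees 1–6.
* PNG masks binarize at intensity > 127 (midpoint of 8-bit range); any
  channel over threshold counts for RGB inputs.
* Polygon rasterization marks a pixel foreground iff its center lies inside
  or on the polygon boundary (boundary-inclusive containment via shapely),
  matched in tests by a crossing-number oracle with an explicit on-segment
  check.
* The min-area rotated rectangle enumerates convex-hull edge orientations
  (the optimal rectangle has a side collinear with a hull edge); collinear
  point sets degenerate to a zero-height rectangle along the principal
  direction. Long side ≥ short side by convention, rotation in [0°, 180°);
  for exact squares the tie keeps the first optimal hull edge found, which
  is deterministic for a fixed mask.
* Curve samples map to pixels by round-half-up in each coordinate.
* If the curve's head entry coincides with the head centroid (degenerate
  axis), θ is defined as 0 and a diagnostic warning is recorded.
* The skeleton baseline fits the line by principal direction (orthogonal
  regression): stems are near-vertical, so regressing y on x would be
  ill-conditioned.
* The MER baseline measures the root mask only, matching the root-tilt task.
* AP integrates precision over recall by trapezoid (extended flat to
  recall 0, padded to recall 1 with precision 0) — numbers are not
  comparable to 11-point or COCO-interpolated conventions.
* Scenes where a method fails are excluded from that method's aggregates and
  counted, rather than assigned a penalty angle.

## Problem sizes

The standard study set is 200 scenes (mixed presets) plus a 200-scene clean
straight stratum; unit oracles run at 100 random instances
(control-point sets, masks) and the KD-tree check at 20 point sets × 200
queries. These sizes give stable aggregate statistics (binomial error on a
200-scene accuracy is ~1 %) while keeping the full suite fast on a single
CPU.

## Known limitations

* Exactly one instance per class per scene; no multi-plant frames.
* The generator's leaf line is perfectly horizontal; real occlusion edges
  are ragged and sometimes slanted. The subtractive-only noise model cannot
  emulate over-segmentation (extra pixels).
* Tangent-based constructions on the curve (auxiliary points sometimes drawn
  in geometric illustrations of the quadratic) play no computational role
  and are not implemented.
* A Hough-transform baseline is not included; the comparison set is MER and
  skeleton only.
* `compare_methods` truth labels derive from the ground-truth angle with the
  same β as the predictions — there is no independent "measured" label
  source, unlike a field study with an inclinometer.
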