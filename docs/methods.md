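# Methods

## Geometry and conventions

The camera frame is x-right, y-down (image rows), z-forward (depth). The rig
is pitched down by the inclinometer angle θ ∈ [0°, 90°), so the world up
direction in camera coordinates is `u_c = (0, −cos θ, −sin θ)`. All public
interfaces use degrees; trigonometry is done in radians internally.

A leaf is reduced to its root→tip chord `A → B` (root = vein pixel nearest
the image top). Two angle definitions are used:

* **α** — the chord's angle to the imaging plane, *positive when the tip is
  nearer the camera than the root*: `α = arcsin((z_A − z_B)/‖B − A‖)`.
* **ϕ** — the LIA, the chord's angle to the horizontal plane:
  `ϕ = arcsin(|(B − A) · u_c| / ‖B − A‖) ∈ [0°, 90°]`.

For chords lying in the vertical plane through the optical axis, on the
physically standard branch (tip pointing down-image and toward a
downward-pitched camera), these close exactly: `θ + α + ϕ + 90° = 180°`.
The sign convention for α is forced by that identity: writing the in-slice
chord as `(0, cos ψ, sin ψ)`, the up-vector definition gives
`ϕ = 90° − |ψ − θ|` while the closure gives `ϕ = 90° − θ − α`; the two agree
on the branch ψ ≤ θ precisely when α = −ψ, i.e. tip-nearer-positive. The
alternative (tip-deeper-positive) closes only at θ = 0.

α is additionally computed by a projective construction: A and B are
projected through the optical centre onto the (unit-focal) imaging plane
giving A′, B′; a point C is placed on the ray from A parallel to A′B′ with
|AC| = d_A·|A′B′| (similar triangles), and α is the angle at A in triangle
ABC by the law of cosines. The construction equals the closed form to
< 1e−9° for in-slice chords (a test asserts this on 1000 random pairs) and is
the path used by the acceptance computation; the default measurement path
takes ϕ from the up-vector form, which is exact for *any* chord orientation,
and back-fills α = 90° − θ − ϕ so that every emitted record satisfies the
closure identity to machine precision.

Degenerate inputs: coincident key points, non-positive depths and chords
along a single optical ray are rejected or routed to the closed form.

## Segmentation

The chain is depth → per-axis forward differences → per-axis local surface
angles → per-axis angle differences → pixel classification → two-pass
labelling → size filtering.

* **Angle conversion.** The metric footprint of one pixel step at depth z is
  `z/f`; the local angle is `arctan(Δz/(z/f))`. This first-order footprint is
  exact at the principal point and degrades gracefully off-axis; since the
  classifier thresholds angle *differences*, the smooth off-axis bias cancels
  on continuous surfaces.
* **Classification.** A pixel is flagged as an edge when its angle difference
  on either axis exceeds `segTh × 90°`. `segTh` is dimensionless and read as
  a fraction of a right angle (the recommended 0.5 ⇒ 45° tolerance), which
  makes the documented sweep from 1 down to 1/80 span "only right-angle
  creases" to "any 1° wobble". Additionally a **steep-angle cut** flags
  pixels whose local angle magnitude is ≥ `steep_cut_deg` (default 80°):
  surfaces nearly parallel to the viewing ray cannot be measured, and such
  readings arise in practice only at depth steps. The steepest legitimate
  surface in the study grid is ~61°, leaving a wide margin.
* **Jump pixels.** `nTh` counts corrupted *depth* pixels that may be jumped:
  a run of m corrupted pixels propagates through one first and one second
  difference into m+2 consecutive flags, so a flag run of length ≤ nTh + 2 is
  a healing candidate (this is the only reading under which a single-pixel
  spike heals at nTh = 2 but survives at nTh = 0, while a clean step — a
  2-flag run — always survives at nTh = 0). A candidate run is healed back to
  surface only if the flanking surface pixels are mutually consistent:
  1. flank angles agree within the tolerance;
  2. the depth chord bridging the gap is itself below the steep cut (a
     near-vertical bridge is a step, not a surface);
  3. the chord agrees with both flank angles within the tolerance.
  Without (2) and (3), a step between two locally parallel surfaces (a leaf
  floating in front of the background) would satisfy the flank test and be
  healed away, merging every leaf with its background. Healing runs per axis
  and clears only that axis's flags; a break seen by one axis survives
  whatever the other axis concludes. Consequence: a 1-px-high horizontal
  mismatch streak is healed completely at nTh ≥ 1 (each column sees a short
  run; the row axis flags only the streak ends), while genuine crease/step
  lines are never healed by any axis.
* **Labelling.** Classic two-pass connected components over surface pixels
  with 4-connectivity (edges must fully enclose a region): pass one assigns
  provisional labels per run and records equivalences in union–find, pass two
  resolves and relabels contiguously. A flood-fill (scipy.ndimage) serves as
  the independent oracle in tests, never as the implementation.
* **Size filter.** Regions outside `[min_area_frac, max_area_frac] × (H·W)`
  are dropped; survivors are relabelled largest-first. Defaults 0.002 / 0.5:
  the lower bound kills specks and mismatch debris while keeping the smallest
  foreshortened leaf of the study conditions (~250 px of a 76 800 px frame);
  the upper bound removes the background plane. Both are package choices —
  the size criterion itself is part of the method, its numbers are not
  prescribed.

## Denoising

Stereo networks emit spatially smooth disparity; i.i.d. synthetic depth noise
is harsher than anything such a backend produces, and raw forward differences
amplify it. The pipeline therefore applies an **edge-preserving 5×5 median
filter** to the depth map before the gradient chain (config `median_radius`,
default 2; an optional Gaussian stage exists, default off, because linear
blur converts depth steps into angle ramps that the classifier then has to
re-detect). Invalid pixels are filled from their nearest valid neighbour for
filtering and re-masked afterwards. The median also removes isolated
double-depth mismatch outliers outright; the jump-pixel rule remains the
defence for structured mismatch runs.

## Key points

The vein support is the opened region (disk structuring element, radius 2 by
default — the paper-scale blade is ≥ 10 px wide, so radius 2 strips
protrusions without disconnecting the blade; the element's shape/size is a
package choice). If opening empties the region the radius falls back to 1 and
then to the raw region. Root = minimum-row vein pixel, tip = maximum-row,
ties broken toward the smaller column; key-point depths are repaired by the
5×5 neighbourhood median when the pixel itself is invalid, and a leaf whose
vein has no valid depth anywhere nearby is skipped with a warning. An
optional skeletonisation of the vein (config flag) exists for strongly curved
leaves; the extreme-row rule needs only the opened mask, so it is off by
default.

## Acquisition front-end

Detection backends are pluggable callables (image → boxes with confidences);
the shipped fixtures are a full-frame detector and a JSON-sidecar reader.
Selection keeps the highest-confidence detection at or above `conf_th`
(default 0.6), ties toward larger area then smaller x0; below-threshold
frames abort with a logged reason. The two stereo boxes are aligned by
symmetric expansion about their centres to the element-wise maximum size,
then shifted (never shrunk) into the image. Depth follows the rectified
pinhole relation `z = f·B/d`, with disparities ≤ `min_disp` (0.1 px) marked
invalid rather than mapped to huge depths.

## Synthetic scenes

The generator renders planar elliptical leaves over a constant-depth
background plane by per-pixel ray–plane intersection, with painter's-rule
occlusion and exact ground truth (masks, root/tip pixels and 3-D points, true
ϕ). The chord direction is built so its angle to the horizontal equals the
requested ϕ for every azimuth; azimuth 0 places it in the vertical plane
through the optical axis, tip down-image and toward the camera — the
configuration in which the closure identity is exact, used by the acceptance
geometry checks.

The reference study conditions (`standard_scene`): 320×240 px, f = 300 px,
baseline 12 cm, background at 3 m (the working shooting distance), leaves of
44×24 px (≈ 0.44 × 0.24 m at that range, a large-bladed crop such as castor)
held ~0.45–0.55 m in front of the background — a plant standing clearly
proud of the ground plane, so every leaf boundary is an unambiguous depth
step. Noise models: zero-mean Gaussian depth noise (σ as a fraction of
depth; 0.5 % ≈ 15 mm at 3 m), isolated double-depth salt pixels (discrete
stereo mismatches; exact count `round(rate·N)`), and 1-px-high double-depth
streaks (continuous mismatch bands), all seeded and reproducible.

What the generator does *not* emulate: leaf curvature and serration, soft
disparity gradients at occlusion boundaries, correlated matching error,
texture-dependent dropout, wind motion. Passing the synthetic recovery grid
therefore demonstrates the geometric and algorithmic correctness of the
chain under clean-to-moderately-noisy depth, not field-grade accuracy on
real canopies, where depth-estimation error dominates.

## Problem sizes and runtime

The recovery checks run 25 scenes (five shooting angles 18.6°–38.7° × five
true LIAs 10°–70°, three leaves each) twice — noiseless and with 0.5 %-of-
depth Gaussian noise plus 0.1 % salt — at 320×240 px; the full suite
completes in a few seconds on one CPU. Oracle-equivalence checks use ≥ 1000
random chords and ≥ 50 random label masks.

## Known limitations

* Overlapping leaves at similar depth merge into one region (the crease
  between them can fall inside the angular tolerance); the method reports the
  merged region's chord.
* Leaves viewed nearly edge-on (|local angle| above the steep cut) are
  discarded as unmeasurable rather than guessed.
* The closure identity is exact only for in-slice chords; out-of-slice leaves
  are handled by the up-vector path, and the recorded α is the closure
  complement rather than an independently constructed quantity.
* `segTh` interacts with surface curvature: strongly curved blades need a
  larger tolerance or the optional skeleton-based vein to keep one region per
  leaf.
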