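# Methods

## The detector

The working image is the display-scaled slice I(x, y) ∈ [1, 256]: HU values
inside the soft-tissue window (width 400, level 40; i.e. [−160, 240] HU)
map linearly onto [1, 256] and values outside clamp to the endpoints. The
floor of 1 (rather than 0) guarantees the ratio's denominator is never
zero. A 5×5 median filter with edge replication suppresses noise; medians
preserve step edges, which is what the detector consumes.

Every pixel is evaluated (the seed image is the image itself — no
initialization). For a seed s and direction θ, the candidate is
c = s + u(θ), where u rounds (cos θ, −sin θ) to a unit grid offset, so
diagonal steps are full pixels and all distances are Chebyshev. Two N×N
blocks are centered at c ± ⌊w/2⌋·u(θ), and

R_c = (C₁ + C₂ − 2 V_c) / (2 V_c),

with C₁, C₂ the block means and V_c = I(c). The block mean is the true
average (1/N² times the block sum). |R_c| ≥ T requires the mean flank
intensity to exceed (1 + T)·V_c — at T = 0.85, flanks 1.85× brighter than
the candidate. The detector is therefore a *dark-line/interface* detector
(its lineage is retinal-vessel line operators): it fires on the hypodense
fat planes and air gaps that delineate abdominal organs, not on gentle
soft-tissue steps, and it is exactly invariant to positive rescaling of
the image.

R_m(s) = max over the 8 directions of |R_c|; the confidence matrix is
C_w = [R_m ≥ T] (inclusive threshold). A border margin of
⌊w/2⌋ + ⌊N/2⌋ + 1 pixels, where the geometry would leave the image, is
flagged invalid and treated as non-edge — the liver never touches the
frame in abdominal CT.

Two readings of the flank placement are possible; the implemented default
puts the blocks *along* the detection direction (the worked-example
geometry). The classic line-operator variant with flanks perpendicular to
the direction is available as `block_orientation="perpendicular"` for
experimentation, without a correctness claim.

The vectorized field computation accumulates the N² shifted images in the
same row-major order as a scalar loop would, so it agrees *bit for bit*
with the naive per-pixel implementation used as a test oracle.

## Postprocessing

1. **Outlier removal** — binary opening of C_w with a 2 px disk. Detected
   boundary bands are ≥ 5 px wide (interface width plus the ±1 px
   candidate offset), so real boundaries survive while speckle does not.
2. **Largest edge network** — 8-connected largest component (diagonal edge
   chains from the 8-direction detector must not fragment). Ties break to
   the leftmost centroid, then the smallest label.
3. **Invert + erode (2 px disk)** — closed contours become interior
   regions disconnected from the background; the erosion severs remaining
   single-pixel bridges.
4. **Body mask M** — Otsu threshold on the display image, a 3 px-disk
   closing (seals ~4 px fat planes that reach the outline at any
   orientation, so the body stays one piece, while a detached ring
   artifact with a moat wider than ~6 px stays separate), largest
   component, opening with a 20 px disk (shaves thin bright appendages
   such as detached ring arcs), then hole filling. Erosion steps treat
   outside-image as foreground so a body reaching the frame is not shaved
   there. Candidate regions are intersected with M.
5. **Anatomical selection** — among components whose centroid column is
   left of 0.6 × width (the liver sits image-left under radiological
   display), the largest wins; if none qualifies, the overall largest is
   returned with a warning. The 0.6 cut-off is a design choice; the
   method's sources give no number.
6. **Restore + smooth** — the selected region is dilated with the same
   2 px disk used in step 3 (the erosion there exists only to disconnect
   regions; without undoing it the final mask is biased ~4 px inward),
   then Gaussian-blurred (σ = 2 px), re-binarized at 0.5, median-filtered
   over a 5 px window to close slits, re-intersected with M, and reduced
   to its largest component so the output is a single connected mask.

Any stage that empties the mask aborts with an error naming the stage.

## Parameters

| name | default | unit | role |
| --- | --- | --- | --- |
| T | 0.85 | — | ratio threshold; plateau of stable accuracy ≈ [0.82, 1.0] |
| w | 9 | px | detection window; flanks sit ⌊w/2⌋ = 4 px from the candidate |
| N | 3 | px | block size for the flank means |
| window_width / window_level | 400 / 40 | HU | display window |
| median_window | 5 | px | denoising median |
| outlier_radius | 2 | px | disk for opening, region erosion and restore dilation |
| ring_radius | 20 | px | disk for the body-mask opening |
| gaussian_sigma / reconnect_window | 2 / 5 | px | boundary smoothing and reconnection |

## The phantom generator

A phantom emulates the structures the detector targets on the HU scale:
an elliptical soft-tissue body (40 HU) on air (−1000 HU), a large liver
ellipse (90 HU) pressed against the left body wall, and an
equal-attenuation neighbor organ (70 HU) pressed against the right wall,
with organs delineated by ~4 px hypodense fat planes (−120 HU), the way
real anatomy separates organs of similar attenuation. Optional features:
a bright ring artifact (300 HU, 3 px thick) as a circle hugging the body
outline, a tumor inside the liver (hypodense 45 HU cancer-like or mildly
hyperdense 115 HU hemangioma-like — tumors count as liver in the truth
mask), additive Gaussian noise (default σ = 10 HU, a typical abdominal CT
level) and salt-and-pepper impulses (default off). Ground truth is the
liver ellipse, exact by construction. `generate_suite` randomizes the
geometry, keeps the wall contacts by construction, and gives a chosen
fraction of phantoms tumors (default 1:1).

Two geometric choices are load-bearing and deliberate. The liver's fat
rim reaches the body outline on the left, and the neighbor reaches it on
the right: this connects the organ-boundary edge web to the body-outline
edge band (so the largest-edge-component stage keeps it) and splits the
intra-body tissue into upper/lower pools each smaller than the liver (so
"largest left component" is unambiguous). Both mirror real axial anatomy.
The fat at −120 HU (display 26.5) makes the weakest link — the rim/air
junction, where one flank is air — fire at ratio ≈ 2.05, comfortably
above the sweep plateau's upper edge T = 1.0; the generic rim ratio is
≈ 4.45.

What the phantom does **not** emulate: partial-volume blur at boundaries,
anisotropic spacing, beam-hardening/strip/motion artifacts, organ texture,
shape variability beyond ellipses, and fat planes that fade or vanish —
on real scans the detector's weak-edge behavior is correspondingly less
forgiving. Passing phantom tests demonstrates the pipeline's mechanics
(detection, separation, selection, artifact rejection), not clinical
accuracy.

Measured behavior worth knowing: the weak-edge limit is reached when the
mean flank display intensity falls below (1 + T) times the interface
display intensity; with defaults the pipeline separates liver from
neighbor at interface −100 HU and fails by −80 HU (pinned in the test
suite). Mean Dice is flat (slightly rising, as noise thins the detected
band and with it the inward bias) up to σ ≈ 60 HU and collapses by
σ = 120 HU, so the noise test asserts a trend (pairwise non-increase with
0.01 slack, strict overall decline), not strict monotonicity.

## Metrics

All metrics are 2D per-slice with masks as pixel sets. Borders are
positive pixels with a background 4-neighbor (outside the image counts as
background). Surface distances pool both directed nearest-border distance
sets in physical units (row/col spacing in mm): ASD is the pooled mean,
RMSD the root mean square, MSD the maximum — hence ASD ≤ RMSD ≤ MSD, and
all three are symmetric. VOE = 100·(1 − |A∩B|/|A∪B|);
SRVD = 100·(|A| − |B|)/|B| is signed, positive meaning oversegmentation.
Undefined ratios (empty classes) are explicit `None`, never silent zeros.
`threshold_sweep` scores a pipeline failure as an empty prediction so
gross failures appear as background-only accuracy instead of aborting.

## Numerical choices and degenerate inputs

* Block-mean normalization is 1/N² (a true average). An alternative
  1/(N−1)² normalization sometimes seen in print does not average and is
  not used; for the ratio it would only rescale both flank terms.
* Display floor 1 (not 0) keeps 2·V_c > 0 exactly.
* Thresholds are inclusive (R_m ≥ T); re-binarization after Gaussian
  smoothing uses ≥ 0.5 (majority).
* Ties: histogram-mode ties resolve to the lowest intensity (warned);
  component-size ties to the leftmost centroid, then the smallest label.
* Constant images fail fast: no edge evidence (detector) and no
  body/background split (body mask), each with a stage-named error.
* Images smaller than 2(w + N) per side are rejected by the detector.
* Problem sizes are chosen for exactness at desk scale: 256² phantoms,
  40² oracle-comparison images, 10-phantom sweep suites.

## Known limitations

* 2D per-slice only; volumes are iterated slice by slice and surface
  metrics are in-plane.
* The anatomical left-region rule fails on situs inversus or atypical
  slices where the liver is not the largest left structure.
* Eq-level ambiguity in the flank placement is resolved by convention
  (see above); the perpendicular variant is untested science.
* Tumors at the liver edge can break the enclosing boundary and are a
  known failure mode; tumor-free liver extraction is out of scope.
* The histogram seed mask is a diagnostic only; the pipeline never uses
  it.
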