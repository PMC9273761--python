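# Methods

This note documents the models, conventions and numerical choices behind
`vasctree`, and what the synthetic fixtures do and do not establish about
real fundus data.

## Coordinate and raster conventions

All in-memory rasters are numpy arrays indexed `(row, col)`, 0-based.  The
MATLAB-style per-image container stores pixel index sets as 1-based
column-major linear indices; conversion happens only at the I/O boundary
(`io_container`).  A/V masks travel as RGB PNGs with an exact palette
(red = artery, blue = vein, green = crossing, black = background); the
palette is matched with zero tolerance so mask round-trips are bit-exact.
The binary vessel mask is by construction the union of the artery, vein
and crossing classes.

The working resolution is a 1024×1024 square: the FOV bounding box is
cropped from the full frame (odd originals first trimmed to even
dimensions by dropping the first row/column, recorded as `dim_change`),
padded with black to a square so the FOV aspect ratio is preserved, then
isotropically resized — bilinear with anti-aliasing for intensity images,
nearest-neighbour without anti-aliasing for masks, because interpolating a
label raster erodes 1-px vessels.  `CropInfo` records every step, so
`restore_full` is an exact geometric inverse (up to the sub-pixel jitter
of nearest-neighbour resampling, verified to < 0.5 % area disagreement in
tests).  Downsampling binary vessel masks by a factor of 3 or more breaks
the topology of 1–3 px vessels and should be avoided.

## Preprocessing

**CLAHE** runs on the luminance channel (Y′ of YCbCr), clip limit 0.01,
tile ≈ 1/8 of the image side.  **Local contrast enhancement (LCE)** is a
per-channel Gaussian high-pass: the background estimate is a
normalized-convolution Gaussian (σ = 25 px at the 1024 scale) computed
from inside-FOV pixels only, and the residual is linearly rescaled to
[0, 255] and recentred at mid-grey.  A flat region therefore maps to a
flat region (a numerical floor of 1e-6 on the residual amplitude prevents
float dust from being amplified); outside-FOV pixels are untouched.  σ
trades off how local "local" is: smaller σ flattens illumination more
aggressively but starts suppressing wide vessels.

**FOV border extension** pads artificial intensities ring by ring outside
the FOV (each new pixel = mean of its 8-neighbours already inside), which
removes the hard black edge that segmentation models mistake for a vessel;
inside-FOV pixels are returned bit-identical.

**Sauvola binarization** of soft vessel probabilities uses
`t = m·(1 + k·(s/R − 1))` with window 25, k = 0.2 and dynamic range
R = 0.5 appropriate for values in [0, 1].  The local threshold tracks the
neighbourhood statistics, so a faint 1-px branch at probability 0.45
survives where a global 0.5 cut drops it.  One consequence of the formula:
on a constant plateau s = 0 and t = 0.8·m < m, so any uniformly positive
region is labelled foreground — meaningful binarization presumes the
model emits near-zero probabilities off-vessel, which confident
segmentation models do.

## Skeleton and landmarks

Skeletonization is Lee's thinning method (`scikit-image`,
`method="lee"`), chosen because it produces 1-px-wide centrelines without
spurs on smooth tubes.  Neighbour counts exclude the centre pixel:
terminals have exactly 1 neighbour, bifurcations ≥ 3.  The raw count
raster is exposed so either centre-inclusion convention can be audited.
Terminal pixels within δ = 20 px of the optic-disc boundary become
starting vertices (distance to the image centre is the fallback when no
disc is given); terminals on the FOV rim are flagged `border_uncertain`
because part of the vessel cross-section lies outside the captured region
and the centreline there cannot be trusted — they are flagged, not
corrected.

## Vascular graph and trees

Skeleton pixels inside the optic disc are removed before graph
construction (central vessels are intertwined; their geometry is not
estimable).  Landmark pixels are deleted, every residual 8-connected run
becomes one segment edge, and 8-connected landmark clusters become
vertices.  Two real bifurcations closer than a few pixels cannot be
resolved as separate branch points, so segments of path length ≤ 3 px
joining two bifurcation vertices are contracted; the merged vertex then
carries ≥ 4 connected edges and is reported as a merged-bifurcation
candidate rather than silently split.

Tree tracking is simultaneous breadth-first region growing from all
starting vertices.  Determinism: at each step the frontier vertex with the
lexicographically smallest (row, col) position (ties to the lower tree id)
is expanded, and incident edges are claimed in edge-id order, first come
first served.  An edge that reaches a vertex already owned by the same
tree stays in the tree's edge set — it closes a graph circle, which the
topology screen then reports: per tree, a minimum spanning tree (weights =
segment path length, diagonal steps √2) of the tree's own undirected edge
set is built, and every tree edge absent from the MST certifies one
circle, reported as the MST path between its endpoints plus the edge.
Components no tree reaches are reported as orphans, not attached.
Strahler orders refuse to run on a cyclic tree (cycle detection first).

## Geometry

Diameters use `d = 2·EDT − 1` (Euclidean distance to background, clamped
≥ 1): for a centred centreline pixel of a width-w tube the nearest
background pixel is ⌈w/2⌉ away, so odd widths are recovered exactly and
even widths within 1 px; the estimator is validated against a
perpendicular cross-section pixel-count oracle (mean absolute error
≤ 1 px over calibres 3–15, measured in the test suite).  The EDT is
inflated where segments meet a junction, so the focal-variation rule trims
roughly one local radius off each end of a segment's diameter profile
before applying its 10-px sliding window — when the segment is long
enough to afford it; short profiles are scanned whole.

Bifurcation angles take, for each of the two child edges, the unit vector
from the vertex to the child's centreline pixel at geodesic distance 10 px
(the circular search area; configurable).  On thick junctions the
rasterized junction blob displaces both the branch-point pixel and the
first few path pixels, biasing the angle by a few degrees; the bias decays
with the search radius and with thinner calibres (quantified in the
acceptance script on a 5-px fixture, recovered within 5° of the drawn
60°).

The vessel tortuosity index is defined in this package as

    VTI = 0.1 · SD_θ · (N_critical + 1) · (L_arc / L_chord)

where SD_θ is the standard deviation (degrees) of the tangent-angle
sequence of the path smoothed with a 5-px moving average (suppressing the
8-connectivity staircase) and unwrapped, N_critical counts strict local
extrema of that sequence (curvature direction reversals), and the last
factor is the arc-to-chord ratio.  A straight segment scores exactly 0; a
single smooth arc has no curvature reversal but nonzero angle spread, so
the +1 keeps it strictly positive; oscillating paths grow with both the
reversal count and the spread.  The index is invariant to rotation,
translation and traversal direction (property-tested).  Closed paths
(chord ≈ 0) are rejected, not scored.

## Quality control

Hole detection floods the background with 4-connectivity (the dual of the
8-connected foreground) and reports background components that do not
reach the raster border, per artery/vein mask separately.  Holes whose
centroid falls inside the optic disc are genuine intertwined-vessel loops
and are reported but never auto-filled.  Small-component analysis reports
8-connected components strictly below 100 px.  Both scans are verified
against per-pixel BFS oracles.  Note one deliberate coupling surfaced by
the fixtures: an interior hole also corrupts the skeleton into a small
loop, so a hole typically triggers both the hole scan and the graph-circle
screen — the reason holes are hunted before topology is trusted.

Label disambiguation is pure set arithmetic inside the FOV: *unlabelled* =
predicted ∧ ¬manual, *mislabelled* = manual ∧ ¬predicted; together they
partition the symmetric difference exactly.  Patch-score aggregation
excludes score-0 (no visible vessel) patches and uses the sample standard
deviation by default (population sd behind a flag, since either convention
is defensible); results are reported as mean ± 2·sd.

## Fractal dimension

Box counting uses dyadic box sizes from 2 px up to half the region
bounding-box side (at least 4 scales), grid anchored at the bounding-box
corner; FD is the least-squares slope of log N(s) against log (1/s), with
the fit R² reported.  Grid-offset averaging exists behind a flag but is
off by default.  FD is computed on the vessel mask by default (skeleton
behind a flag).  The standardized macula region is a disk centred on the
macula with radius 0.6× the macula-to-disc centre distance.  On dyadic
test sets the estimator is essentially exact (line 1.000, filled square
2.000, depth-7 Sierpinski gasket 1.58496 = log 3/log 2); on non-dyadic
regions the ceiling effects of partial boxes can bias the slope by a few
hundredths.

## Segmentation metrics

All metrics count FOV pixels only — out-of-FOV pixels are trivially
background and inflate every pixel-wise score (regression-tested by
planting noise outside the FOV).  Dice = 2|P∩G|/(|P|+|G|), defined as 1
when both masks are empty; it equals F1 bitwise.  AUPR integrates the
exact precision-recall curve step-wise (Σ ΔR·P, no trapezoids, which are
optimistically biased for PR curves) and matches an exhaustive threshold
sweep to 1e-9.  A ground truth with no vessel pixel inside the FOV is an
error, not a score.

## Synthetic fixtures: what they show and what they do not

The generator renders perfect binary trees as envelopes of disks along
analytic centrelines — the same tubular model that motivates
skeletonization — with calibres in the realistic 1–20 px range, geometric
child/parent width ratio 0.8 (so healthy fixtures obey the parent ≥ child
calibre rule), configurable bifurcation angle and sinusoidal tortuosity,
and deterministic output per seed.  Default study conditions: 512² raster,
depth 3, root calibre 11 px, 60° bifurcations, segment length 110 px
shrinking by 0.75 per level.  Injected defects (loop, interior hole,
isolated small component, near-coincident bifurcations 2 px apart, border
spur) are registered in the ground truth, so detector sensitivity *and*
specificity are both testable.

Passing on fixtures establishes the correctness of the algorithms under
the tubular model: exact topology recovery, Strahler orders equal to the
rule applied to ground truth, defect detection with no cross-talk beyond
the physically real couplings noted above.  It does not establish
performance on real fundus images, whose vessels have intensity-dependent
edges, central light reflexes, crossings between arteries and veins,
pathology (lesions, neovascularization) and annotation noise far richer
than the injected defects.  The toy fundus renderer (textured disk,
radial illumination falloff, darker vessels, blurred noisy probability
map) exercises the enhancement and binarization code paths but is not
photometrically realistic.

## Problem sizes

Test fixtures use 512² rasters (one 2848×4288 frame exercises the crop
path), trees of depth ≤ 5, random oracle rasters ≤ 64², and 1024² rasters
for fractal dimension; the full suite runs in well under a minute and the
acceptance script in a few seconds, with every stochastic draw seeded.
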