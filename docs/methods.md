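# Methods

`cslight` implements a one-shot coded structured light (CSL) pipeline for
metric 3D reconstruction of smooth, fusiform subjects (the motivating
application is live fish, whose mobility rules out multi-shot patterns).
This note records the model, the choices made where the design was open,
and the limits of what the synthetic test harness demonstrates.

## Pattern code

The projected pattern is a lattice of `cols x rows = 76 x 43` binary
symbols on a 1920x1080 canvas.  Each symbol is a 20x20 px glyph from a
6-letter alphabet — rectangle, L, T, triangle, X, Π — placed on a 25 px
pitch (5 px gaps).  Every 3x3 window of symbols (a *subpattern*) is
flattened row-major into a 9-symbol *codeword*; the lattice is constructed
so that all `(rows-2)(cols-2) = 3034` codewords are at pairwise Hamming
distance ≥ 3.  A distance-3 code lets the decoder correct exactly one
symbol error per codeword: a word within distance 1 of a book entry has a
unique nearest entry (two entries within distance 1 of the same word would
be within distance 2 of each other).

*Generation.*  The lattice is filled in raster order by seeded randomized
backtracking: placing the symbol at `(r, c)` with `r, c ≥ 2` completes
exactly one 3x3 window, and a candidate symbol is accepted only if that
window's codeword keeps distance ≥ 3 to every previously completed window
(vectorized scan over the partial book).  Dead ends backtrack
chronologically; a node budget (500k) triggers a restart with a derived
seed.  Generation is deterministic in `(rows, cols, seed)`; the default
76x43 lattice generates in well under a second and its exhaustive
all-pairs scan (~4.6M comparisons, blocked in NumPy) confirms a minimum
distance of exactly 3.

*Flattening order.*  Any fixed bijection between the 3x3 window and the
9-tuple preserves Hamming distances, so the choice (row-major) only has to
be shared between encoder and decoder.

*Known limit of a distance-3 code.*  Double errors are not always
detectable: the default book holds ~3.2 neighbors per codeword at distance
exactly 3, so a random double error lands within distance 1 of a *different*
codeword with probability ≈ 1% and is then (consistently with the
acceptance rule) decoded there.  Measured over 100 seeded random double
flips, 99 are rejected and 1 is mis-accepted.  Downstream, such rare wrong
codewords are further screened by the positional-consistency rule (a symbol
decoded at inconsistent lattice positions by overlapping codewords is
dropped).

*Glyph geometry.*  Stroke width 4 px; the triangle and rectangle are
filled.  The six glyphs were sized so that every distinct pair scores at
least 0.7 under the normalized dissimilarity below (measured minimum 0.756,
at the triangle–X pair); the constraint is re-verified at construction
time and a violation raises.

## Binarization

Captured images are converted to grayscale (ITU-R 601 luma) and
adaptively binarized with Sauvola's rule: per-pixel threshold
`t = m (1 + k (s / R - 1))` with `m, s` the local window mean/standard
deviation and `R = 128` the dynamic-range constant.  Three practical
choices matter:

- **Polarity.**  Sauvola's rule was designed for dark text on light paper,
  where the threshold hugs the local mean from below.  Pattern captures are
  bright-on-dark, so the threshold is computed on the photometrically
  inverted image (`255 - I`) and the comparison inverted back.  Applied in
  the textbook direction the threshold sits only slightly above the dim
  background and sensor noise crosses it freely.
- **k = 0.1, window 31 px.**  Document-image practice (k ≈ 0.2–0.5)
  assumes text occupies a sparse minority of each window; here a window
  that contains a symbol is balanced bimodal, so the cut belongs near the
  local mean, i.e. small k.  The 31 px window slightly exceeds the symbol
  pitch at the working distance (~26 px), so local statistics always mix
  symbol and background.
- **Minimum-contrast guard (`min_std`, pipeline default 25).**  In windows
  with no signal at all (unlit background) `s ≈ 0`, the Sauvola threshold
  degenerates and, under noise, up to half the pixels come out foreground;
  a percolated multi-thousand-pixel blob results.  Windows whose `s` is
  below the guard carry only sensor noise (≤ ~16 gray levels across the
  10–16 dB band, vs ≥ ~40 for any pattern-bearing window) and are forced to
  background.  Set `min_std=0` for the plain rule.

Foreground is labeled by 8-connected components (thin diagonal strokes of
the X must not fragment); components under 50 px are rejected as noise, and
the pipeline additionally drops blobs over 5000 px, which cannot be single
symbols at the working geometry (~140–320 px).

*Otsu comparison.*  A global-threshold variant (`use_otsu=True`) exists for
controlled comparisons.  Under the simulator's shading (foreground 230,
background 25 before degradation) the contrast ratio is ~9:1, so a 2x
multiplicative illumination ramp still leaves the dimmest foreground
(~115) far above the brightest background (~25): *any* global threshold
separates the classes and Otsu is not handicapped (measured decode rates
0.985 Otsu vs 0.973 Sauvola at the 13.68 dB operating point).  The
documented failure of global thresholding on real captures involves surface
reflectance variation spanning a much larger dynamic range; in this
simulator the adaptive advantage only appears for ramps approaching the
contrast ratio (≥ 4x).  The corresponding acceptance check asserts the
strict adaptive > global ordering under a 2x ramp and is left failing as a
faithful record of this discrepancy.

## Symbol classification

Each component is matched against all 6 classes over a rotation sweep
θ ∈ [-22°, +22°] in 1° steps (45 variants per class).  Every rotated
template's bounding-box content is anisotropically rescaled to the
component's bounding box ("elongated or shrunken" per the ratio of the box
sides), and scored by the normalized sum of absolute differences

    SAD(X, Y) = Σ |X - Y| / max(ΣX, ΣY) ∈ [0, 2],

i.e. the pixel disagreement normalized by the larger foreground count.
The component takes the class of the global arg-min; ties break to the
lowest class id, then the smallest |θ|.  Rotation and rescaling use
bilinear interpolation re-thresholded at 0.5 — nearest-neighbor mapping can
fragment the X's thin diagonals, which must stay 8-connected across the
sweep.  Rotation+scale (no projective search) is justified by the low
surface curvature of fusiform bodies away from their outline.

Scaled template stacks are cached per bounding-box size; components on a
lattice share few distinct sizes, which keeps full-scene classification in
the seconds range.

## Subpattern topology

For each symbol with at least 8 detected neighbors, the 8 nearest (by
centroid distance, ties broken lexicographically) are traversed by a
nearest-unvisited chain from the center.  The chain closes the four
overlapping 2x2 quads of the 3x3 neighborhood after 3, +2, +2 and +1
visits: with visits `v1..v8`, the quads are `{c, v1, v2, v3}`,
`{c, v3, v4, v5}`, `{c, v5, v6, v7}`, `{c, v7, v8, v1}`.  Corner roles are
assigned greedily — repeatedly pair the globally closest (point,
bounding-box-corner), remove both — at two levels: to the four quad
centroids, and to the four members of each quad.  The corner rules then
place all nine symbols; each edge-middle symbol is determined twice and the
center four times, and any disagreement invalidates the candidate
(`dual_check` / `quadruple_check`).  Additional rejections: a chain step
longer than 1.8x the median step length (`chain_break`, the declared
failure of the 8-nearest assumption, which the source method leaves
unquantified), and point sets without a convex-quadrilateral hull
(`degenerate`).

The greedy corner assignment equals the exhaustive minimum-total-distance
bijection over all 4! = 24 assignments for quadrilateral-like
configurations — verified exactly on 1000 lattice cells jittered up to 30%
of the pitch, the regime the pipeline operates in.  For *uniformly random*
point quadruples the two rules genuinely differ (~80% agreement); such
configurations do not arise from a detected symbol lattice and no
optimality claim is made there.

## Decoding and correspondences

Valid arrangements are flattened and matched against the codeword book:
exact hits decode at distance 0; otherwise a vectorized scan accepts a
unique distance-1 match and identifies the offending symbol.  Each such
correction is applied to the symbol's class label *globally*, which lowers
the distance of every other codeword containing it; decoding iterates to a
fixed point (bounded by the symbol count; the accepted set grows
monotonically).  Conflicting corrections (different codewords implying
different classes for one symbol) abstain and are logged; distance-0
acceptances are never revised.

One correspondence is emitted per distinct decoded image symbol (a symbol
is fully decoded when it appears in ≥ 1 decoded codeword); the pattern-side
point is the symbol's rendered centroid, the image-side point the component
centroid.  Symbols implied at inconsistent lattice positions by overlapping
codewords are dropped.  A per-symbol participation count (0–9 codewords)
serves as the boundary-loss diagnostic: interior symbols of a large lattice
participate in 9 codewords, outline symbols in fewer.

## Triangulation and morphometrics

The rig model is pinhole-pinhole: camera at the origin (x toward the
projector, y down, z along the optical axis), projector at
`(baseline, 0, 0)` yawed toward the camera axis by a convergence angle.
Defaults: baseline 53.4 cm, camera 3328x2496 px at 78.7° horizontal FOV,
projector 1920x1080 px at 42.5° horizontal FOV, working distance ~72 cm.
Focal lengths in pixels follow as `f = (W/2) / tan(hfov/2)`.  The
convergence default of 20° aims the projector at a point ~27 cm in front of
the camera axis at 72 cm, where both frusta overlap on a fish-sized target;
the true rig value is not published and the parameter is exposed in the
calibration.

A correspondence is triangulated as the midpoint of the common
perpendicular between the camera and projector rays; the segment length
(skew distance) is kept as a per-point quality measure, and near-parallel
ray pairs or negative-depth solutions are rejected.  The pipeline further
gates points on skew (default 0.05 cm, ~1.5 px of off-epipolar error at
the default rig): geometrically consistent pairs triangulate with skew in
the 0.01 cm range even under sensor noise, while wrongly decoded pairs —
the rare survivors of the coding checks — show skew from ~0.06 up to
several cm and would otherwise inject gross depth outliers into the
morphometrics.  On noiseless synthetic
correspondences the pipeline reproduces ground-truth depth to ~1e-14 cm
(pure floating-point error); the first-order depth sensitivity at the
default geometry is `dz ≈ z²/(f·b) ≈ 0.05 mm` per pixel of centroid error.

Total length and height are the extents (max − min) of the point cloud
along its first two principal axes (eigenvectors of the point covariance).
Max−min matches the "total length" convention of fish measurement; a
percentile option (e.g. 1st–99th) is available for noisy clouds.  Sparse
symbol-level sampling underestimates extents near the outline; the bias
shrinks with symbol density.

## Synthetic scenes

The simulator replaces live-fish captures.  For every camera pixel the
camera ray is intersected with a parametric surface and the hit point
projected into projector coordinates, where the rendered pattern raster is
sampled (inverse mapping: no splat holes).  Surfaces:

- fronto-parallel **plane** at depth 72 cm (default extent 40x30 cm, a
  target-board stand-in; the clean-decode acceptance scene uses 78x42 cm so
  the full pattern footprint lands without truncating any symbol);
- **ellipsoid** with semi-axes (15, 5.5, 2) cm — a fusiform stand-in sized
  like a ~30 cm x 11 cm fish — centered one semi-axis behind the nominal
  depth, so its front surface spans depths from 72 cm.

Both are centered on the projector's optical axis at the working depth.
Shading is foreground 230 / background 25; degradations, in order, are a
horizontal multiplicative illumination ramp (1 → 1/g), Gaussian blur
(default σ = 1.5 px, mild defocus), and additive Gaussian noise scaled to a
target SNR, defined as `10 log10(var(clean image) / var(noise))` — the
operating band 13–16 dB matches published live-fish captures, and the
default operating point is 13.68 dB.  The realized SNR of a render is
reported and lands within 0.5 dB of the request.  All randomness flows from
`SceneConfig.seed`; identical configurations render bit-identically.

Ground truth comprises per-pixel depth and, for every symbol, the exact
camera-image point of its rendered centroid (obtained by casting the
projector ray of that centroid and re-projecting the surface hit), so
decode rate, false matches, centroid error and depth RMSE are measured
against geometry, not against the pipeline itself.

*What the simulator does not model:* surface texture (scales, fins, eyes),
reflectance variation, specularities, occlusion by other objects,
underwater refraction, lens distortion, and motion blur.  Passing tests
demonstrate the geometric and coding machinery under controlled noise and
illumination — not robustness to biological appearance variation.

## Problem sizes in the test suite

The suite favors exhaustive checks at small scale: a 10x10 lattice (64
codewords) for brute-force distance scans and decoder constructions, the
full 76x43 pattern for the structural scan and end-to-end scenes, and
full-resolution (3328x2496) renders for the handful of scene tests, with
sweeps (SNR, jitter) at reduced lattice sizes.  Classifier accuracy is
assessed on 300-trial batches per condition.
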