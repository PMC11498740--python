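# Methods

This note documents the models, conventions, numerical choices and
limitations behind `spheremark`.

## Camera model and conventions

The camera is a pinhole with Brown–Conrady distortion. Conventions, all of
which are choices (other toolchains differ) and are fixed package-wide:

* **Pose** maps world to camera, $X_c = R X + t$; $R$ must be orthonormal
  with det +1 (checked to 1e-9). The camera center is $C = -R^\top t$.
  This matches the common photogrammetry export convention; an importer
  dialect (`camera_to_world`) inverts exports that store $(R_{cw}, C)$
  instead.
* **Camera frame**: right-handed, +z forward. Points with $z_c \le 0$
  cannot be projected and raise `NonPositiveDepth`.
* **Pixels**: origin at the top-left corner, x right, y down, continuous,
  0-based, integer coordinates at pixel centers.
* **Distortion**: radial $k_1, k_2, k_3$ and tangential $p_1, p_2$, all
  defaulting to 0. Real calibration exports often carry only a subset;
  absent coefficients are zero.

Undistortion has no closed form; it is solved by fixed-point iteration
$p \leftarrow p_d - (\mathrm{distort}(p) - p)$ starting from the distorted
value, tolerance 1e-10, at most 100 iterations (`NoConvergence` beyond
that). For lens-like coefficient magnitudes the map is a strong
contraction and converges in a handful of iterations; the round trip
re-projects to the source pixel well below 1e-6 px.

## Triangulation

Each observation back-projects to a ray $(o_i, d_i)$, $\lVert d_i\rVert=1$.
The landmark estimate minimizes $\sum_i \mathrm{dist}(x, \text{ray}_i)^2$,
whose normal equations
$\big(\sum_i I - d_i d_i^\top\big) x = \sum_i (I - d_i d_i^\top) o_i$
are solved directly (3×3 symmetric system). The system is singular iff all
rays are parallel; we raise `DegenerateGeometry` when the smallest
eigenvalue is below 1e-9 × the largest — conservative for double
precision. All views are weighted equally.

The linear closest-point solve is the default and primary method. A
Gauss–Newton refinement of the pixel reprojection error (numeric Jacobian,
≤ 20 iterations) is available behind `refine=True`; for narrow-baseline
spheres of near-identical cameras the two agree to well below measurement
precision, so the simpler estimator is the default. The per-landmark
quality metric is the RMS reprojection error over the observing views.

## Scale and measurement

Bundle-adjusted geometry fixes shape but not scale. The calibration token
— two landmarks a known physical distance apart, default 6.69 mm — gives
$s = L_{known} / L_{model}$ in mm per model unit. Reported distances are
$s \lVert a - b \rVert$ rounded to 0.01 mm, the precision of a digital
caliper, using **half-up** decimal rounding (bit-stable via `decimal`,
ties away from zero). Rounding is applied only at the reporting/CSV layer;
all internal arithmetic is full precision, because compounding rounding
would corrupt downstream statistics. The token landmarks are ordinary
landmarks named in the calibration record; no hexagon geometry is fitted.

## View navigation

The view sphere stores, per camera, the unit vector from the sphere center
to the camera center; the center is the **centroid of camera centers**,
which is robust for near-uniform acquisition spheres (and exact for the
synthetic generator, whose lattice is recentered). Nearest-view retrieval
maximizes the dot product with the normalized query — equivalent to
minimum angular distance — with ties broken by smallest camera id so
results are reproducible. Longitude/latitude queries use the math
convention $(\cos\phi\cos\lambda, \cos\phi\sin\lambda, \sin\phi)$ with
latitude in [−90°, 90°].

## Project format and I/O

The canonical format is one versioned JSON document (cameras with
intrinsics and poses inline, landmarks with observations and positions,
optional scale calibration, standard views). Floats are serialized at full
`repr` precision, keys sorted, so identical projects are byte-identical
and write→read is lossless. Photographs are referenced by relative path
and never opened. The two-file import (JSON sensor intrinsics + CSV
extrinsic rows) covers the common photogrammetry export layout; its
`camera_to_world` dialect inverts poses on entry. CSVs use comma
separators, UTF-8 and `.` decimals; pandas reads them with
`float_precision="round_trip"` so coordinate round trips are exact. The
landmark export (`label,x,y,z,x_mm,y_mm,z_mm`) writes model units at full
precision and mm at 0.01; without a calibration the mm columns equal the
model columns (s = 1).

## Comparison statistics

For replicate series of one distance measured by technique × operator:

* diff to reference: $100 (\bar x_{tech} - \bar x_{ref}) / \bar x_{ref}$,
  computed operator-against-same-operator;
* inter-operator: $100 (\bar x_A - \bar x_B) / \bar x_B$, operators in
  lexicographic order;
* dispersion: $100 (\max - \min) / \text{mean}$ over the pooled replicates
  of both operators.

Per-specimen aggregation averages the signed diffs per operator, then the
two operator averages. The global summary sums |diff| over every
(specimen, distance, operator) cell; by construction the cumulated value
equals count × absolute average. The repeatability summary uses the sample
(n−1) standard deviation and a 95% interval $\bar x \pm t_{0.975, n-1} s$
— a prediction-style band for individual repeats, chosen because it
matches published interval widths for such series where a standard-error
interval does not. Micro-CT is the conventional reference technique
(`uCT` in the bundled tables, where the sphere-of-images workflow is
labeled `Sphere`).

The bundled fixtures are replicate values published rounded to 0.01 mm;
statistics recomputed from them therefore match published derived cells to
about ±0.01 on their printed scale, and a few published cells (derived by
their authors from unrounded raw data) are not exactly recoverable — the
tests assert only the recomputable ones.

## Synthetic scenes

The generator emulates a gimbal acquisition: `n_cameras` on a Fibonacci
lattice (recentered so the lattice centroid is the sphere center to ~1e-13)
at `sphere_radius`, each posed to look at the origin; specimen points
uniform in an ellipsoid with semi-axes (1, 0.75, 0.5) × `specimen_extent`;
the token pair exactly `token_separation_mm / mm_per_unit` model units
apart. Observations are true projections plus i.i.d. isotropic Gaussian
pixel noise, kept only when in front of the camera and inside the frame.
Everything derives from one seeded `numpy` generator, so identical specs
produce byte-identical projects.

Defaults: 30 cameras, radius 50 model units, specimen extent 5, scale
2 mm/unit (a ~10 mm insect imaged from ~100 mm), token 6.69 mm, intrinsics
preset 5472×3648 px with f = 14500 px (a 20 Mpx-class sensor behind a long
macro lens — deliberately loose; only the ratios matter for the geometry
under test). Noise-free scenes validate exactness (point recovery below
1e-6 of the radius, token recovered to 0.01 mm through the full
generate→write→read→triangulate→calibrate→measure loop); the noise study
uses σ = 0.5 px over 10 seeds on 30-camera spheres and observes median
relative distance errors far below 1% — an idealized bound, since real
error budgets add landmark-picking ambiguity, stacking distortion and pose
error, none of which the generator models. What passing these tests shows
is that the estimator chain is correct and numerically stable, not that
any particular real acquisition reaches this accuracy.

Problem sizes in the tests and the acceptance script (≤ 30 cameras,
≤ 20 points, 10 seeds) keep full runs in the seconds range while leaving
every code path exercised.

## Known limitations

* No outlier rejection or per-view weighting in triangulation; a single
  bad pick degrades the estimate (the RMS reprojection error flags it).
* Fisheye/omnidirectional lenses and rolling shutter are out of scope;
  poses and intrinsics are consumed, never estimated.
* Semi-landmarks, angles and areas are not measured; the export is a plain
  coordinate table.
* The undistortion fixed-point solver is not guaranteed for extreme
  distortion coefficients (it raises rather than returning garbage).
* The comparison statistics implement fixed formulas; no hypothesis
  testing or mixed-effects repeatability modeling is provided.
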