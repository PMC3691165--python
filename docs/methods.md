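# Methods

`dentopo` quantifies the three-dimensional topography of a tooth crown from
two triangle meshes — the outer enamel surface (OES) and the enamel–dentine
junction (EDJ) — and relates the two surfaces geometrically. This note
documents the model, the numerical choices, and what the synthetic test
surfaces do and do not establish.

## Coordinate frame and alignment

Every computation assumes a canonical frame. It is constructed from three
anatomical landmarks, the dentine-horn tips at the protocone, paracone and
metacone on the EDJ:

1. the plane through the three tips is rotated into the xy plane, with the
   sign chosen so the tips lie above the crown's z-centroid (occlusal side
   up: +z runs from cervix to occlusal relief);
2. the mesial axis — protocone tip → paracone tip — is rotated parallel to
   +x, with +x pointing from protocone to paracone (the parallelism
   constraint fixes the line, not the sign; the sign is our convention and
   is recorded in the transform metadata);
3. the centroid of the three tips is placed at x = y = 0;
4. each mesh is independently shifted in z so its own lowermost cervix
   vertex sits at z = 0, making crown height a positive z reading.

Step 4 means the OES and EDJ may receive different vertical shifts (their
cervices need not coincide, and on offset-built synthetic crowns they do
not). Elevation-based quantities use these per-mesh frames; enamel
thickness, which is a property of the *pair*, is always measured in the
common frame (the per-mesh z shifts undone). Right-side teeth are mirrored
in x before alignment so quadrant labels remain comparable; the mirror flag
travels with the transform.

Alignment is idempotent and all signifiers are equivariant in the expected
way: area and curvature are rigid invariants, elevation shifts with z,
orientation rotates with the frame.

## Per-polygon signifiers

For each face: area υ (half cross-product), barycenter χ, elevation
γ = χ_z, unit outward normal **n**, and

* **orientation ψ** — azimuth of **n** in the xy plane, counter-clockwise
  from +x viewed from +z, on [0°, 360°). Faces with
  hypot(n_x, n_y) < 1e-8 are flagged *undefined* and excluded from
  orientation binning rather than forced into a bin.
* **inclination λ** — implemented as 180° − angle(**n**, +z), equivalent to
  the tangent-vector definition and numerically simpler: 180° for
  horizontal up-facing polygons, 90° for vertical walls, < 90° for
  re-entrant (overhanging) surfaces that 2.5-D projections cannot see.
* **mean curvature φ** — mean of the two principal curvatures, estimated by
  a per-vertex least-squares quadric fit (five coefficients) over the
  2-ring neighborhood in the local tangent frame; the face value is the
  mean of its three vertex values. Sign: convex toward the outward normal
  is positive. The estimator is validated against closed forms: within 2 %
  of 1/R on a unit sphere, 5 % of 1/(2R) on a cylinder, and |φ| < 1e-3 on a
  plane interior at the default resolutions. Faces touching an open
  boundary are flagged — their one-sided neighborhoods make the fit
  unreliable — and excluded where curvature enters indices.
* **standardized curvature φ_std** = φ · (V^⅓ / V_ref^⅓), with V the volume
  enclosed between the surface and its base plane z = 0 (divergence theorem
  with F = (0,0,z); vertical closure walls and the base contribute
  nothing). The published description of the standardizing "volume of
  OES/EDJ" is ambiguous; enclosed-against-base volume is our documented
  choice. With no reference given, each surface is its own reference and
  φ_std = φ.

## Enamel thickness and correspondence

Thickness δ at each OES vertex is the minimum Euclidean distance to the
nearest EDJ triangle — exact point-to-triangle distance, not a vertex or
normal-ray approximation. The query uses a KD-tree on triangle centroids
with a certified expansion radius (d_best + max centroid-to-vertex radius),
so results are identical to an exhaustive all-triangles scan (asserted to
1e-9 mm in tests). Per-face δ is the mean of the three vertex values
(unbiased and resolution-stable); the face-level correspondence matrix
assigns each OES face the EDJ face nearest its barycenter — one
deterministic match per face. Degenerate EDJ triangles are excluded with a
warning.

## Re-tessellation

Crown meshes are rebuilt at a target face count (default 22,000) with
near-uniform, tooth-size-standardized polygon areas, by isotropic explicit
remeshing at target edge length L = √(4A/(√3·N)): iterative long-edge
splitting at shared midpoints (no T-junctions), independent-set short-edge
collapsing guarded by the link condition and a maximum-edge bound, and
tangential Laplacian relaxation with projection back onto the original
surface. A control loop rescales L by √(count/target) until the face count
is within ±5 % of target. Boundary (cervix) vertices are never collapsed
and are held fixed during relaxation, preserving the cervix polyline. On
smooth synthetic crowns the output retains ≥ 99.9 % of the input area; the
face-area coefficient of variation lands near 0.25.

## Orientation patches and complexity

Orientation is binned half-open at 45° (eight bins; the width is
configurable and must divide 360°). Patches are maximal *edge*-connected
components of same-bin faces — vertex adjacency would chain patches through
pinch points. Components with fewer than `min_patch_size` faces are
discarded; the threshold is retained inclusively at its default of 3 faces
and, because patch counts are resolution- and threshold-dependent, both the
face count and the threshold are attached to every complexity output rather
than normalized away.

## Indices

With ROI masks applied (the occlusal region: faces whose barycenter lies at
or above the plane through the lowermost basin point of each surface;
auto mode takes the lowest vertex inside the xy projection of the tip
triangle):

* δ mean/sd are area-weighted; δ^st = Σδᵢυᵢ / A_EDJ divides by the EDJ
  occlusal 3D area instead, making it a standard thickness comparable
  across crowns;
* occlusal relief index Γ = Σ(υγ | λ > 135°) / Σ(υγ | λ < 135°); faces
  exactly at the threshold are excluded from both sums (a measure-zero
  choice, documented for determinism);
* classic relief index = 3D area / planimetric area of the occlusal
  projection, computed on the union of projected triangles so overlapping
  projections (overhangs) are counted once;
* crest threshold: the 90th percentile of the positive φ_std values of the
  reference surface (the specimen's own EDJ by default) — "crest" has no
  published numeric definition, so a fixed, reported rule is used and
  recorded in every output;
* φ^p (relative crest area), φ^mci (area-weighted positive φ_std over
  area), φ^bi = φ^p_EDJ / φ^p_OES (> 1 when enamel blunts the junction),
  relative complexity ψ^c-e/d = ψ^c_OES / ψ^c_EDJ, relief accentuation
  Γ^OES/Γ^EDJ, and scale-free thickness δ_mean / V_dentine^⅓.

## Covariation

Each OES occlusal face contributes a row (δ; γ, λ, ψ, φ of the OES face;
the same four of its matched EDJ face). Correlations between configured
variable pairs are computed on subsamples drawn with replacement — default
130 subsamples of 1000 rows — reporting per-subsample Pearson r and the
fraction significant under a two-sided t test at α = 0.01. Orientation is
circular but is correlated linearly for comparability with the published
profiles; results involving ψ carry an explicit circularity note. All
resampling is seeded and bit-reproducible.

## Synthetic surfaces

The generator provides the ground truth that absent specimen scans cannot:

* analytic primitives (plane, sphere, hemisphere, cone, cylinder,
  concentric shells) with closed-form signifiers, used as curvature,
  orientation-uniformity, cap-area and thickness oracles;
* crown pairs: the EDJ is a height field over an elliptical footprint
  (paraboloid dome + four Gaussian cusps − a Gaussian central basin) and
  the OES is the EDJ offset along its vertex normals by the thickness
  field, so generated enamel thickness is known exactly and recovery can be
  asserted (within 1 % for constant fields at default resolution).

Defaults emulate an anthropoid upper second molar: 11.2 × 10.4 mm
footprint, ~2–3 mm of basin-to-cusp relief, 0.6 mm occlusal enamel
(mid-range for medium-sized anthropoids; the tightest concave groove radius
of the default crown is ≈ 0.73 mm, and the generator rejects any thickness
that folds the offset surface), and 22,000-face surfaces matching the
standard analysis resolution. Optional seeded vertex jitter supports noise-
robustness experiments on patch counts.

What the synthetic surfaces do *not* emulate: enamel pinching out at the
cervix (the offset rim extends below the EDJ rim instead), wear facets,
crenulation, perikymata-scale texture, or realistic taxon shape spaces.
Passing recovery tests therefore demonstrates correctness of the geometry
pipeline, not biological realism of any particular index value.

## Problem sizes and determinism

Tests run the pipeline at 4,000–12,000 faces and the re-tessellation
checks at 40,000–60,000 input faces; the acceptance script uses a
100,000-face crown decimated to 22,000, the standard analysis resolution.
All randomness (generator jitter, resampling) flows from explicit seeds;
repeated runs produce byte-identical CSV/JSON outputs, and every output
file carries the configuration hash and package version.

## Known limitations

* The quadric curvature estimator degrades on meshes far from isotropic;
  re-tessellation first is assumed.
* The planimetric union area uses exact polygon union (GEOS); extremely
  degenerate projections (perfectly vertical ROIs) are rejected rather
  than patched.
* ψ^c is reported with its resolution and threshold because no canonical
  normalization exists; comparisons across resolutions are the user's
  responsibility.
* Landmark placement error propagates directly into the frame; no
  wear-robust alignment alternative is provided.
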