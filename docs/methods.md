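# Methods

## The pipeline

A segmented muscle arrives as a 3D integer label map with anisotropic voxel
spacing (default 0.65 × 0.65 mm in-plane, 2.0 mm slice thickness — typical
reconstructed axial MRI). The slice axis is the third array axis; a
`distal_end` flag records which end of that axis is anatomically distal, and
all downstream quantities are invariant to flipping the axis together with
the flag.

1. **Per-slice areas.** The ACSA of slice *i* is its labelled voxel count
   times the in-plane voxel area. Only occupied slices count; axial holes in
   the segmentation are retained in the span with zero area and a warning.
   Multiple connected components within a slice are summed.
2. **Muscle length.** L = (occupied span in slices) × slice thickness. Each
   slice represents a full dz-thick slab, so a single occupied slice has
   length dz and L is consistent with the volume bookkeeping
   MV = Σ area × dz (which equals voxel count × voxel volume exactly).
3. **Normalized profile.** Slice centers map to relative positions
   (i − i_min + 0.5)/N on (0, 1); areas are linearly interpolated onto a
   101-point grid (one value per 1% of muscle length, 0% distal, 100%
   proximal), with constant extrapolation beyond the outermost slice
   centers. Linear interpolation is the least-assumption choice at 2 mm
   slice spacing; the grid resolution itself (1%) is the method's standard.
4. **ACSA_max.** Argmax on the 101-point grid. Exact ties resolve to the
   plateau midpoint (rounded down to the grid) — the only orientation-
   symmetric deterministic rule; a constant profile reports location 0.50.
   Real profiles essentially never tie, so the rule matters only for
   degenerate phantoms.

## Estimators

**Shape factor.** p = MV/(L × ACSA_max) ∈ (0, 1] for any profile whose
areas are bounded by ACSA_max. `ShapeFactorVolume.fit` stores the
per-subject p values, their mean p_avg and sample SD, and the cohort-mean
ACSA_max location x̄. `predict` returns p_avg × L × ACSA(x̄): the
in-practice variant, which needs only one measured cross-section per
subject at a standard site. An `ideal` mode samples each subject's own
ACSA_max instead; with the subject's own p it inverts the definition and
reproduces the reference volume to machine precision (an identity the test
suite checks). Fitting is self-estimation over the full cohort by default;
a `leave_one_out` flag excludes each subject from the averages used for its
own estimate. p_avg is a plain arithmetic mean.

**Truncated cone.** Five slices at relative positions 1.00, (1 + x̄)/2, x̄,
(x̄ + 0.01)/2, 0.01 (indices descending distally; the 0–1% slab is never
counted, so a constant profile yields exactly 0.99 × L × A). Segment
volumes use the conical-frustum quadrature d/3 × (A_i + A_{i+1} +
√(A_i·A_{i+1})), which is exact for any shape whose equivalent radius is
linear in x (cones, frusta) — a property the tests verify to < 0.5% on
voxelized phantoms, the residual being rasterization and grid
interpolation. Positions are evaluated at full precision on the
interpolated 101-point profile, not snapped to acquisition slices.
For unimodal profiles every sampled area is ≤ ACSA_max, so the estimate
never exceeds 0.99 × L × ACSA_max; since fusiform radius profiles are
concave between the sampled sites, the method systematically
underestimates — with small between-subject spread, the precision half of
the accuracy/precision trade-off.

**Agreement.** Relative difference = 100 × (ref − est)/mean(ref, est)
(classical Bland–Altman denominator for ratio-scale data; positive =
underestimation; a `reference` denominator is available — with ~10%
differences the two differ by ≲ 1 point). Bias is the mean difference, SD
the sample (n−1) standard deviation, limits of agreement bias ± 1.96 SD.
No regression-based limits, no confidence intervals on the limits.

## Phantoms

Phantoms are straight, axis-aligned solids with elliptical cross-sections
(default semi-axis ratio 1.5 — muscle sections are not circular; the
parameterization solves both semi-axes from the target area, so the ACSA
profile is unaffected). Families: cylinder, cone (apex distal), frustum
(linear radius), and the fusiform `beta_spindle`

    A(x) = A_max · (x/x_m)^(α−1) · ((1−x)/(1−x_m))^(β−1),
    α = 1 + κ·x_m,  β = 1 + κ·(1−x_m),

whose mode is exactly x_m and whose volume has the closed form
A_max · L · B(α, β)/(x_m^(α−1)(1−x_m)^(β−1)); every closed form is verified
against adaptive quadrature to 1e−8 relative tolerance in the test suite.
Voxelization labels a voxel iff its in-plane center lies inside the ellipse
at its slice-center's axial coordinate — no partial-volume weighting,
matching how binary label maps behave — and converges to the analytic
volume as spacing shrinks (tested over a monotone three-step refinement).

**Cohort defaults** emulate a 39-subject vastus-lateralis-like athlete
cohort: L ~ N(400, 25) mm, A_max ~ N(4000, 500) mm², peak location
~ N(0.61, 0.0965) truncated to [0.05, 0.95] (truncation keeps peaks off the
muscle ends), voxel spacing (0.65, 0.65, 2.0) mm. The sharpness default
κ = 2.407 was solved once so that the analytic shape factor at x_m = 0.61
equals 0.62, the published VL value; together with MV ≈ 0.62 × 400 × 4000
≈ 992 cm³ this matches the reported VL magnitudes. All randomness flows
from a single integer seed; a cohort is bit-identical under the same seed.

What the phantoms do **not** emulate: segmentation error (outlining noise,
partial-volume ambiguity), curved centerlines (the per-slice method is
centerline-agnostic, but real ACSA planes are oblique to curved muscles),
multi-muscle interfaces, and any intensity-level MRI artifact. Passing
tests therefore demonstrate correctness of the estimators' arithmetic and
their geometric biases, not robustness to segmentation quality on real
images.

## Numerical choices and degenerate inputs

- Profiles need ≥ 2 occupied slices; estimator fitting needs ≥ 2 subjects.
- The truncated-cone anchor must satisfy 0.01 < x̄ < 1.00 (outside, the
  five positions degenerate).
- Zero-SD cohort distributions are honored exactly (all subjects share the
  template value) rather than drawn.
- Shape validation rejects nonpositive lengths/areas/spacings, negative κ,
  and peak locations outside (0, 1).
- Voxel grids are capped at 2×10⁸ voxels to catch accidental micron-scale
  spacings.
- Problem sizes in the tests and the acceptance script (L = 300 mm solids
  at MRI spacing, n = 39 cohorts at the default spacing) were chosen as the
  smallest sizes at which discretization error is comfortably below the
  properties being demonstrated.

## Known limitations

- The beta-spindle is this package's shape model; real muscles are not
  constrained to it, and realistic per-muscle κ values are unknown — κ is
  calibrated only for the VL-like default.
- Muscle length from slice span inherits ± one slice thickness of
  uncertainty; at 2 mm slices and L ≈ 300–400 mm this is < 1%.
- The estimators assume the anchor location x̄ comes from the same cohort
  (self-estimation) unless leave-one-out is enabled; transfer to a new
  population is not modeled.
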