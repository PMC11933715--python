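# musclevol

Muscle volume (MV) quantification from 3D label maps of segmented muscles,
for researchers and practitioners in sports science and rehabilitation who
need MV faster than full slice-by-slice segmentation allows.

The reference method outlines a muscle on every axial MRI slice; its volume
is the labelled voxel count times the voxel volume. `musclevol` implements
that reference bookkeeping plus the two time-efficient estimators used in
practice, and quantifies their agreement:

**Shape-factor method.** The dimensionless shape factor

```
p = MV / (L × ACSA_max)
```

(L = muscle length, ACSA_max = maximal anatomical cross-sectional area) is
nearly constant within a muscle across a population — exactly 1 for a
cylinder, 1/3 for a cone, ≈ 0.62 for the vastus lateralis. Given a cohort
mean `p_avg` and the cohort-average location `x̄` of ACSA_max along the
muscle (fraction of length, 0 = distal), a subject's volume is estimated
from a single cross-section:

```
MV_sf = p_avg × L × ACSA(x̄)
```

**Truncated-cone (frustum) method.** Five cross-sections are sampled — at
1% and 100% of muscle length, at `x̄`, and halfway between `x̄` and each end
slice — and the volume is the sum of the four frustum segments

```
MV_tc = Σ  d_i/3 × (A_i + A_{i+1} + √(A_i·A_{i+1}))
```

with `d_i` the inter-slice distances in mm.

Agreement with the slice-by-slice reference is summarized per muscle by
Bland–Altman statistics on relative differences (bias, SD, and limits of
agreement bias ± 1.96 SD; positive = underestimation).

Because real MRI cohorts are rarely shareable, the package includes a
phantom generator: voxelized fusiform muscles with closed-form ACSA
profiles and volumes (cylinder, cone, frustum, and a beta-function spindle
whose peak area, peak location and length vary across simulated subjects),
providing exact ground truth for every stage of the pipeline.

## Worked example

Simulate a 39-subject cohort of spindle phantoms emulating a vastus
lateralis (length ~ N(400, 25) mm, ACSA_max ~ N(4000, 500) mm², peak
location ~ N(61%, 9.65%) of muscle length) and run the full pipeline:

```python
from musclevol import RunConfig, run_pipeline

cfg = RunConfig(simulate={"n_subjects": 39}, out_dir="out", seed=1)
res = run_pipeline(cfg)
s = res.cohort_summary.iloc[0]
print(f"p_avg = {s['p_mean']:.3f} +/- {s['p_sd']:.3f}")
print(f"ACSA_max location = {s['acsa_max_location_pct_mean']:.1f} +/- "
      f"{s['acsa_max_location_pct_sd']:.1f} %")
print(res.agreement.table.round(2).to_string(index=False))
```

which prints

```
p_avg = 0.615 +/- 0.025
ACSA_max location = 59.6 +/- 9.2 %
          muscle         method  bias_pct  sd_pct  lloa_pct  uloa_pct  n
synthetic_muscle   shape_factor      4.02    5.04     -5.87     13.91 39
synthetic_muscle truncated_cone     13.27    0.94     11.42     15.11 39
```

The cohort statistics recover the generating parameters (shape factor
≈ 0.62, peak location ≈ 61%, up to sampling error at n = 39). The two
estimators show opposite strengths: the shape-factor method has the smaller
bias (better accuracy) but wider limits of agreement, while the
truncated-cone method systematically underestimates — fusiform profiles are
concave between the five sampled slices — yet with much tighter limits
(better precision). `out/` receives `per_subject.csv`, `cohort_summary.csv`,
the agreement tables, and the effective config for provenance.

The same pipeline runs on real data: point `RunConfig(input_dir=...)` (or
`musclevol run --config run.yaml`) at a directory of NIfTI-1 label maps with
a `{label: muscle}` mapping. `phantom generate` writes simulated cohorts as
NIfTI plus a ground-truth CSV manifest; `musclevol agree` recomputes the
Bland–Altman table from any per-subject CSV.

## Layout

- `musclevol.phantoms` — phantom specs, analytic profiles/volumes, voxelization, cohort simulation
- `musclevol.profile` — per-slice ACSAs, muscle length, 101-point relative-length profile, ACSA_max
- `musclevol.estimators` — `ShapeFactorVolume` and `TruncatedConeVolume` (scikit-learn style fit/predict)
- `musclevol.agreement` — relative differences, Bland–Altman summaries, cohort tables
- `musclevol.pipeline` / `musclevol.cli` — end-to-end runs, YAML config, `musclevol` and `phantom` commands

See `docs/methods.md` for the model assumptions, parameter choices and
limitations.
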