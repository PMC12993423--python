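# Methods

## The estimation problem

A fractionated prostate course delivers a plan computed once on the
planning CT (pCT). Daily imaging yields organ contours in the session's
own frame plus the rigid couch-correction matrix applied at setup.
`doseaccum` estimates per-session and accumulated organ doses under two
assumptions:

1. **The planned dose distribution is spatially invariant.** Daily
   anatomy moves through a fixed dose field; the field itself is not
   recalculated. This is justified when tissue-density changes are small
   (pelvis), and it is what makes the method run in seconds per session.
2. **Rigid transfer suffices.** The online matrix maps daily coordinates
   into the planning frame; residual deformation is not modelled
   (deformable registration is explicitly out of scope).

## Pipeline

For each session: (i) every requested contour stack is mapped through the
4×4 registration (moving→fixed by default; a manifest flag declares the
direction, and matrices are inverted on load if needed); (ii) the contour
stack is rasterized onto a common evaluation grid in the planning frame —
the dose grid resampled to isotropic 1 mm (configurable); (iii) the
planned dose is sampled trilinearly at every structure voxel centre;
(iv) DVHs, ICRU-83 metrics and geometry metrics vs baseline are computed.
The planning-target surrogate (prostate + 10 mm uniform margin, built
with an anisotropic-spacing-aware Euclidean distance transform) is
regenerated from each day's prostate rather than copied from the plan,
so it tracks the daily gland.

### Rasterization

Contours are closed planar polygons. A voxel belongs to a structure when
the majority of its supersample × supersample sub-centres (default 4×4;
ties count as inside) fall inside an odd number of the slice's polygons —
the even-odd rule, so nested contours create holes. Along z the slab
model applies: each evaluation slice takes the polygons of the nearest
contour plane within half the contour-plane spacing, i.e. each contour
represents a slab as thick as the slice spacing of the source image.
Measured on analytic shapes at 1 mm: a 25 mm sphere rasterizes to within
0.2 % of 4/3·π·r³ (supersample 2 was measured at +1.2 % and rejected as
the default). Rotational registrations re-slice the contour stack by
resampling a rasterized mask; pure translations (the common online
correction) shift vertices exactly.

### DVH and metrics

Metrics come from raw dose samples, not binned curves: D_x% is the
(100−x)th percentile with linear interpolation between order statistics
(midpoint convention), V_xGy an exact counting fraction, the mean an
arithmetic mean. Cumulative curves (default 0.1 Gy bins) are kept for
display, export and accumulation. Voxel centres outside the dose grid are
excluded and counted; more than 5 % outside (configurable) raises, which
tolerates truncated daily scans while catching gross frame errors.

### Accumulation

With N planned fractions each delivering 1/N of the plan, and assuming
volume fractions are exchangeable across sessions, the accumulated
cumulative DVH equals the equal-weight mean of the daily cumulative DVHs
on a common dose axis in plan-total Gy. Accumulated mean dose and V_xGy
are therefore exact means of the per-session values; accumulated dose
percentiles are read from a pooled fine histogram (0.01 Gy bins) of the
per-session samples with equal session weights — the same estimate at
negligible discretisation cost and bounded memory. Deviations are
normalised to planned values; for the dose percentiles the baseline is
re-read through the same histogram estimator so that a course whose
anatomy never changes deviates by exactly zero (the reported baseline
metrics themselves stay raw-sample-based; the two agree within one
0.01 Gy bin). A metric whose planned value is zero gets a missing
deviation, not zero. Deviations beyond the relevance threshold (default
2 %) are flagged. Partial courses use the available-session mean and
report `n_available`.

### Statistics

CV uses the sample (n−1) standard deviation. Pearson r is pooled over
all sessions of all supplied courses without a clustering correction for
sessions nested in patients (the pooled n is reported so the caveat is
visible). Cohen bands: |r| < 0.3 weak, > 0.5 strong, boundary values
moderate — the literal reading of the conventional strict inequalities.
Quartiles interpolate linearly between order statistics; `summarize`'s
auto style switches to median/IQR when |skewness| > 1.

## The phantom

The generator emulates the study conditions of a hypofractionated
prostate protocol — 60 Gy in 20 fractions — with convex analytic shapes:

| structure | shape | default size | ~volume |
| --- | --- | --- | --- |
| prostate | ellipsoid | 25/20/20 mm semi-axes | 42 cm³ |
| bladder | sphere | r = 36 mm | 195 cm³ |
| rectum | elongated ellipsoid | 16/16/68 mm | 73 cm³ |
| body | elliptical cylinder | 115/85 mm | — |

Interfractional change per session:

* organ volumes scale by unit-mean log-normal factors with σ_log =
  √ln(1+CV²), calibrated to CV targets of 35 % (bladder), 21 % (rectum),
  10 % (prostate), 2 % (body) — the variability magnitudes reported for
  clinical prostate cohorts;
* the prostate centroid moves by a 3-D Gaussian with SD 2.13 mm per axis,
  i.e. a mean 3-D displacement of 2.13·2√(2/π) ≈ 3.4 mm;
* the bladder fills superiorly from an (approximately) fixed base, and
  the rectum distends radially (radius ∝ √s, length fixed) away from its
  fixed anterior wall. These anchorings are the anatomically plausible
  model *and* the mechanism behind the observed inverse volume-dose
  relation: centroid-anchored isotropic inflation would push the near
  organ wall into the high-dose region and flip the correlation sign.
  Purely axial growth was also rejected because a 3 mm contoured slice
  stack cannot observe it (slice quantization);
* a rigid setup error (Gaussian, SD 2 mm per axis) translates *all*
  structures and is recorded inversely in the emitted registration
  matrix, so applying the matrix restores everything except the true
  anatomical change — the post-correction situation the pipeline sees in
  the clinic.

The planned dose is a plateau with sigmoidal falloff,
`D(p) = D₀ / (1 + exp((ρ(p) − ρ₀)/w))`, where ρ is the prostate-
normalised ellipsoidal radius, ρ₀ = 2.0 and w = 0.2 (≈ 4–5 mm falloff in
millimetres). The plateau is wide enough that the baseline prostate mean
dose sits within 1 % of the prescription by construction, while bladder
and rectum lie on the falloff so their doses respond smoothly to motion
and filling. This is not a beam model: only the structure-on-dose
evaluation is under test, matching the method's own premise of reusing
the baseline dose.

What the phantom does **not** emulate: imaging noise and contouring
error (contours are exact analytic cross-sections), organ deformation
beyond affine scaling/translation, intra-fraction motion, density
changes. Passing the phantom suite therefore validates the computational
chain — transfer, rasterization, sampling, accumulation, statistics —
not robustness to contouring quality on real cone-beam images.

### Oracle

A rasterization-free reference: scrambled Sobol points in the shape's
bounding box, rejection-filtered with the exact membership test, dose
interpolated at the survivors. Uniform-dose regions reproduce the dose
exactly; doubling the point count moves phantom-organ metrics by well
under 0.2 % of prescription. Pipeline accumulated metrics agree with the
pooled oracle within a small fraction of a percent of the prescription
(tested at 1 % tolerance).

## Numerical choices and degenerate inputs

* Dose files store 32-bit integers at a 1 mGy quantum; round trips are
  exact to one quantum. Contour vertices are written at µm precision.
* Descending dose slice order is normalised to ascending with an explicit
  warning; nonuniform slice offsets (tolerance 1 mm × 10⁻³) raise.
* Rigidity of registrations is enforced at 1e-4 on the rotation block;
  non-axial image orientations are rejected (tolerance 1e-3).
* DSC with both masks empty is an error (a pipeline fault), one empty
  mask gives 0 (true disagreement). Volume deviation with a zero
  baseline is missing, not 0.
* `accumulate` sorts sessions by index internally, making the result
  exactly permutation-invariant.
* Problem sizes used in the shipped tests and acceptance script — 20- and
  200-fraction courses, 10⁵ oracle points per organ per fraction, five
  phantom patients — were chosen as the smallest sizes at which the
  statistical tolerances above are comfortably resolved.

## Known limitations

* Rigid transfer cannot represent differential organ deformation; the
  method inherits this from its premise.
* Geometry metrics are computed in the planning frame after correction,
  i.e. they quantify *residual* anatomical change, not raw daily
  displacement before setup correction.
* The accumulated-DVH estimator assumes volume-fraction exchangeability
  across sessions; systematic within-organ gradients that track specific
  sub-volumes would need voxel-wise accumulation.
* Pooled correlations ignore patient-level clustering.
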