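# Methods

## Signal model and T2 estimation

Each voxel of a multi-echo spin-echo (MESE) series is modeled as a
mono-exponential transverse decay, `S(TE) = S0 · exp(−TE/T2)`, sampled at
the protocol's seven echo times (10–70 ms in 10 ms steps, TR 2700 ms, voxel
0.3125 × 0.3125 × 3.0 mm).  TR is carried for provenance only: at fixed TR
the T1 weighting is a constant factor absorbed into S0.

The first echo is excluded from fitting.  In MESE trains, imperfect
refocusing pulses generate stimulated-echo pathways whose net effect is a
disproportionate change of the first echo's amplitude relative to the pure
T2 decay of the later echoes; dropping echo 1 removes that contamination at
the cost of one sample.  The synthetic generator models the contamination
minimally — a multiplicative inflation `(1 + bias)` of echo 1 only — which
is exactly what first-echo exclusion neutralizes; the tests demonstrate that
with the echo kept the fitted T2 is skewed and with it dropped the truth is
recovered exactly in the noiseless case.

Estimation is trust-region nonlinear least squares on (S0, T2), initialized
from the ordinary-least-squares line fit of log-intensity vs TE over the
positive intensities (fallback S0 = max intensity, T2 = 40 ms when fewer
than three echoes are positive).  Bounds are T2 ∈ [1, 1000] ms and
S0 ∈ [0, 10 × max intensity]; a solution on a bound is flagged
non-converged rather than trusted.  Goodness of fit is
R² = 1 − SS_res/SS_tot with SS_tot about the mean of the echoes actually
used; R² is undefined (NaN) for constant observations.  Voxels are fitted
independently — no spatial regularization — so results cannot depend on
traversal order.  Voxels with R² < 0.66 (strict inequality) or without
convergence are marked invalid and carry NaN, never a silent zero.

Properties of the estimator worth knowing: at a noise SD of 2% of S0 the
per-voxel T2 standard deviation is ≈ 2.4–3.0 ms (matching the Cramér–Rao
bound for this six-echo design), the median is unbiased, and the mean
carries a small positive skew bias of ≈ +0.3% because T2 enters the model
nonlinearly.  Layer means inherit that +0.3%; tests that bound plate-mean
recovery use phantom sizes (tens of thousands of voxels per plate × layer)
chosen so the Monte-Carlo part of the error is small against the bound.

## Laminar (depth-wise) analysis

Normalized depth is `d_bone / (d_bone + d_surface)`, where the distances
are Euclidean (mm, anisotropic spacing honored) from the voxel center to
the nearest labeled bone-interface and articular-surface voxel.  Distances
are computed per sagittal slice by default, because the slice thickness
(3 mm) is roughly ten times the in-plane resolution and sagittal sections
are the native processing plane; a volumetric transform is available as
`method="edt-3d"`.  Depth 0 sits at the bone interface, 1 at the surface.
Voxels that are simultaneously bone interface and surface (single-voxel-
thick cartilage) get depth 0.5 and are logged.

The 50/50 layer split assigns superficial to depth > 0.5 and deep to
depth ≤ 0.5.  The tie at exactly 0.5 goes to deep — an arbitrary but
documented convention that matters only for discretization-boundary voxels.
A depth threshold (rather than equal per-column voxel counts) was chosen
because it is well defined for any geometry, including curved shells where
"columns" are ambiguous.

The femoral plates are restricted to a weight-bearing region of interest
before averaging: per sagittal slice, the contiguous anteroposterior run of
columns starting at the trochlear-notch landmark and spanning a fraction
(default 0.6) of the condyle extent.  The exact extent used by the
reference analysis is defined in external software, so the fraction is a
config parameter recorded in provenance, not an assertion about that
definition; ROI(f) is nested under increasing f by construction.

Plate × layer summaries are means of T2 over valid ∧ ROI ∧ layer voxels,
with valid and total counts recorded; an empty valid set yields an
undefined (NaN) mean as a data state, not an exception.  The knee-level
value is the unweighted mean of the four plate means (MT, LT, cMF, cLF);
a voxel-count-weighted variant exists behind a `weights` argument.  The
unweighted form was chosen because it reproduces the published Avg rows
from the published plate rows within rounding.

## Synthetic data

**Phantoms.**  Plates are extruded 2D shapes: rectangular slabs (tibia-like)
and upper-half annular shells (condyle-like, bone at the inner radius).
They are deliberately not anatomical — the pipeline is geometry-agnostic
and the tests need exact ground truth more than realism.  True depth is
computed by exhaustive all-pairs distances to the boundary voxels — the
same definition as the pipeline but a different algorithm, so agreement is
a genuine cross-check.  The through-thickness T2 profile is either linear
in depth or a two-compartment step at depth 0.5; default levels are the
published healthy plate means (deep 31.0–39.7 ms, superficial
41.6–49.6 ms).  The forward model applies the first-echo inflation and adds
Gaussian noise (default SD 2 at S0 = 100, i.e. 2% — the source acquisition's
noise level is not published, so this is a testability choice, comfortably
inside the regime where the fit is well behaved).  Rician magnitude noise
is available behind `noise_model="rician"` since magnitude MRI noise is
Rician; Gaussian is the default because at SNR ≈ 50 the difference is
negligible and Gaussian keeps the fit's error analysis clean.

**Cohorts.**  Subject tables follow the published three-group structure:
group sizes 28/32/89 (follow-up 26/24/89), demographics (age, BMI, sex
fraction) per group, and per plate × layer baseline T2 and one-year change
drawn as normals from the published means/SDs.  Change is drawn
independently of baseline by default (only change summaries are published);
a Gaussian-copula correlation is available via `baseline_change_corr`.
Each cell is drawn independently — cross-plate within-subject correlations
are not modeled, so tests exercise one cell at a time.  Optional linear
covariate effects (ms/year of age, ms/(kg/m²) of BMI, ms for female sex,
referenced to age 57 and BMI 26) let tests inject genuine confounding: with
a nonzero age coefficient and the groups' published age gap (healthy
55.0 ± 7.5 vs riskROA 61.1 ± 9.4 y), the crude contrast absorbs the age
effect and the ANCOVA must remove it.  The confounding demonstrations use
0.4 ms/year, set by an analytic power calculation so the adjusted estimate
beats the crude one in ≈ 98% of replicates.

All generators take explicit seeds and share no global random state;
identical spec + seed is bit-identical output.

**What passing tests do and do not show.**  Phantoms have piecewise-constant
or linear T2, sharp boundaries, no partial-volume averaging, no B1 or
slice-profile effects, and exact segmentations; cohorts are exactly normal
with no missingness and no within-subject cross-plate correlation.  Passing
therefore validates the computational pipeline — model inversion, geometry,
statistics — not the biological accuracy of T2 as a composition marker or
the behavior of the method under segmentation error.

## Statistics

Between-group inference defaults to the pooled-variance Student t (CI and
p from the pooled SE at df = n_a + n_b − 2).  Pooled, not Welch, because
the reference study's printed CI for the −2.7 ms superficial contrast is
reproduced exactly by the pooled form (Welch yields [−4.0, −1.4] instead of
[−3.8, −1.6]); Welch sits behind `equal_var=False`.  Cohen's D is the mean
difference over the pooled SD, without small-sample (Hedges) correction —
the printed effect sizes (1.04, 0.81, 0.96, 0.73) are consistent with this
form given that the inputs are printed rounded to one decimal.  The
`comparison_from_summary` route computes the identical inference from
means/SDs/n alone, and agrees exactly with the sample route when fed
matching summaries.

The ANCOVA is OLS of the outcome on a two-level group indicator plus age,
sex (female = 1) and BMI, without interactions; the reported estimand is
the group coefficient with its t-based CI and p (covariate centering does
not affect it).  Rank-deficient designs raise an error naming the
offending columns.  Bonferroni significance (strict p < 0.05/6) applies to
the six primary knee-level baseline comparisons; plate-level and
longitudinal tests are exploratory at descriptive p < 0.05, mirroring the
reference analysis plan.

Longitudinal change is per-subject year-1 minus baseline on subjects with
both visits, tested against zero with the one-sample t; the layer contrast
is the per-subject superficial-minus-deep change, same test.

## Numerical choices and degenerate inputs

- Fits need ≥ 3 echoes after exclusion (an R² over 2 points is vacuous);
  fewer raises.  All-nonpositive voxels return a non-converged result.
- Zero SS_tot → R² NaN → voxel invalid under any threshold.
- `apply_quality_filter` is idempotent and can only shrink validity.
- Zero pooled SD: difference 0 gives d = 0 and p = 1; nonzero difference
  raises (undefined effect size).
- The sex indicator uses exact label match `"female"`; cohort CSVs are
  schema-checked (column set, visit/layer vocabularies, uniqueness of
  (subject, visit, plate, layer), follow-up ⊆ baseline) before use.
- Pipeline outputs embed the config hash; identical config + seed gives
  byte-identical CSVs.

## Problem sizes

Defaults were sized so the full test suite and the acceptance script each
run in minutes on one core: demonstration phantoms use 1–8 extruded slices
(≈ 2,000–17,000 cartilage voxels), the end-to-end recovery check 64 slices
(≈ 133,000 voxels), null calibration 2,000 simulations, and cohort-recovery
checks 300–500 replicate cohorts at the study's group sizes.

## Known limitations

- The weight-bearing ROI is a parameterized stand-in for an externally
  defined region; only its qualitative behavior (nesting, span) is
  asserted.
- No Bloch-equation simulation of the MESE train: stimulated echoes are a
  single-echo inflation, adequate for testing exclusion but not for
  studying refocusing-angle effects.
- Cross-plate and baseline–change correlations default to zero; variance
  of derived quantities that mix cells (e.g. a subject's Avg computed from
  plates) would be understated if computed from these cohorts.
- DICOM ingestion, automatic segmentation, cartilage thickness morphometry
  and T2 texture analysis are out of scope.
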