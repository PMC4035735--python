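# Methods

## Model and procedure

The pipeline treats longitudinal brain change as a per-subject scalar
field of log proportional volume change (the log-Jacobian of the
baseline→follow-up warp) and asks whether a baseline subject-level
measurement predicts that change voxel by voxel.

1. **Jacobian stage.** For a displacement field `u` (mm) on the image
   grid, the mapping is `x ↦ x + u(x)` and the volume-change factor is
   `det(I + ∇u)`. Derivatives are central differences in the grid
   interior and one-sided at boundaries, computed in physical units so
   anisotropic voxels are differentiated correctly. The log transform
   makes no-change exactly 0; maps are scaled by `2.0/ΔT` to a nominal
   2-year interval, valid under log-linearity of change in time.
2. **Voxelwise stage.** Single-predictor OLS with intercept at every
   mask voxel; the slope t is computed through the algebraically
   equivalent correlation form `t = r√(n−2)/√(1−r²)`, which is
   numerically stable and lets a permutation batch be one matrix
   product. Clusters of `t > 3.5` under 26-connectivity are tested by
   maximal-statistic permutation of the predictor (maps fixed): with a
   single regressor and intercept this is an exact exchangeability
   scheme under the null. The critical size is the
   `⌈0.95·n_perm⌉`-th order statistic of the per-permutation maximum
   cluster size; significance requires a strictly larger observed
   cluster. Corrected per-cluster p-values use
   `(1 + #{null max ≥ size}) / (1 + n_perm)`.
3. **Region and cohort stage.** The union of significant clusters is
   summarized (volume, ROI overlaps as a percentage of each atlas ROI,
   tissue composition against a labeled segmentation) and its
   per-subject mean change becomes a derived brain factor for the
   cohort models: OLS multiple regression with demographic terms,
   Pearson factor correlations, and Cox proportional-hazards conversion
   models (Efron ties, one Z-scored brain factor per model,
   likelihood-ratio tested against the model without it, Wald CIs on
   the log-HR scale).

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `t_threshold` | t units | 3.5 | cluster-forming threshold of the voxelwise test |
| `n_perm` | count | 1000 | resolution of the permutation null (≥ 100 enforced) |
| `alpha` | — | 0.05 | familywise level; critical size = 95th percentile of null maxima |
| `connectivity` | — | 26 | 3-D neighborhood for clustering (6/18/26 supported) |
| `clamp_eps` | determinant units | 1e-6 | floor for non-positive determinants before the log; clamped voxels are flagged, not fatal |
| `ΔT` | years | from the subject table | never inferred from file metadata |
| `effect_beta` | log-J per predictor Z (2-yr scale) | 0.02 | planted slope of the generator |
| `bg_mean` | log-J (2-yr) | −0.02 | diffuse background loss (~2% tissue over 2 years) |
| `noise_sigma` | log-J | 0.05 | white-noise SD *before* smoothing |
| `smooth_fwhm_mm` | mm | 6 | spatial correlation of the noise field |
| `delta_t_range` | years | (1, 3) | interscan intervals; scans at least a year apart |
| `predictor_mean/sd` | FA units | 0.35 / 0.05 | plausible tract-FA distribution |
| `hr_per_z` | hazard ratio | {fornix_fa: 0.38} | planted conversion effect per Z |
| `baseline_hazard` | 1/year | 0.04 | ≈18% conversion over a 5-year horizon |
| `censor_time` | years | 5 | administrative censoring for non-converters |

## What the generator emulates — and what it does not

The generator reproduces the *statistical* structure the analysis
assumes: spatially smooth change maps, an effect region linear in the
predictor, log-linear time scaling (so 2-year normalization is exact by
construction), independent demographics, and exponential
proportional-hazards conversion. It does **not** emulate registration
error, template-space anatomy, spatially varying noise, boundary
effects at CSF interfaces, partial-volume mixing, or correlation
between demographics and the predictor. Passing tests therefore
demonstrate that the estimators are correct and calibrated under the
assumed model, not that real acquisitions satisfy those assumptions.

The generator simulates log-Jacobian maps directly rather than
displacement fields: ground truth is then exact and statistical checks
are decoupled from numerical differentiation error. A secondary
analytic path (`scaling_displacement_field`, uniform scaling with
closed-form determinant `s³`) exercises the field→Jacobian route end to
end.

## Numerical choices

- **Non-positive determinants** are clamped to `clamp_eps` and flagged
  in the map's validity mask; a folded voxel must not abort a cohort
  run, and the clamp count is recorded in the output sidecar.
- **Degenerate regressions:** constant voxels get t = 0; perfect-fit
  voxels are capped at t = 1e6 and flagged, so infinities never reach
  the cluster labeling.
- **Max-statistic vs pooled null.** The per-permutation *maximum*
  cluster size is the default null statistic (familywise control); a
  pooled-cluster-sizes mode exists behind `pooled=True` for comparison.
  The test is one-sided (`t > threshold`) by default, matching the
  direction of interest for an integrity-type predictor; a two-sided
  mode is available.
- **Ties:** the critical size is an attained order statistic and
  significance requires strict inequality — conservative under ties.
  Cox ties use the Efron approximation. In brute-force comparisons the
  partial likelihood is compared at 1e-6 while the coefficient is
  compared more coarsely, since the likelihood is flat near its
  optimum.
- **Ethnicity** is treatment-coded with the most frequent level as
  reference, identically in the survival and regression models.
- **Seeding:** each cohort flows from one integer seed through a single
  `numpy` generator; experiment-level studies spawn per-replicate seeds
  from a base seed via `SeedSequence`, so every study is a pure function
  of its arguments.

## Problem sizes used by the shipped studies

The calibration study uses 200 null cohorts of 40 subjects on 20³ grids
with 500 permutations each; the recovery study uses 10 effect cohorts
of 60 subjects with the planted slope set to the smoothed-noise SD
(per-subject SNR ≈ 1, derived from the generator's impulse response,
not hand-picked); the Cox coverage study uses 100 cohorts of 500
subjects, effectively uncensored. These sizes make each study a pure,
quick-to-rerun function of its base seed while keeping Monte-Carlo
margins small relative to the properties being checked.

## Known limitations

- Estimating the deformation field itself (registration, template
  construction) is out of scope; fields or change maps are inputs.
- The voxelwise model is single-predictor by design; covariate
  adjustment happens at the region level, not voxelwise (no
  Freedman–Lane scheme).
- No threshold-free cluster enhancement or cluster-mass statistics.
- Cox models assume proportional hazards and right-censoring only; no
  competing risks or time-varying covariates.
- Masks are combined by exact grid identity; no resampling beyond
  nearest-neighbor semantics, no probabilistic ROIs.
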