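# atrophymap

Analysis pipeline linking baseline white-matter microstructure to
longitudinal voxelwise brain-tissue change in elderly cohorts, with
nonparametric cluster-extent inference and survival models of cognitive
conversion. Written for neuroimaging researchers who have per-subject
longitudinal deformation fields (or precomputed change maps) plus a
baseline subject table, and want a tested, fully reproducible route from
those inputs to cluster statistics, region composition, and hazard
models — exercisable end to end on synthetic cohorts with planted ground
truth.

## The method

**Volume change.** A longitudinal warp `x ↦ x + u(x)` aligning a
subject's baseline scan to follow-up has local volume-change factor
`J(x) = det(I + ∇u(x))`; values in (0, 1) are shrinkage, > 1 expansion.
The analysis works with `log J` (0 = no change, negative = tissue loss)
and, because change is roughly log-linear in time, rescales each map by
`2.0/ΔT` (ΔT = interscan interval in years) to a common 2-year scale.

**Voxelwise inference.** At each voxel the normalized `log J` values are
regressed on a scalar baseline predictor (e.g. mean fractional
anisotropy of a fornix ROI); the slope's Student t (n − 2 df) forms a
t-map. Voxels with t > 3.5 are grouped into connected clusters, and
cluster extent is tested by maximal-statistic permutation: the predictor
is shuffled across subjects, the max cluster size recorded per
permutation, and observed clusters larger than the 95th percentile of
that null declared significant (familywise p < 0.05). Their union is
the significant-association region, whose mean change becomes a derived
per-subject brain factor.

**Cohort models.** The derived factor feeds (i) a multiple regression
on the predictor plus age, gender, education, ethnicity; (ii) a factor
correlation matrix; (iii) Cox proportional-hazards models of conversion
from normal cognition, one brain factor per model (HR per Z-unit,
likelihood-ratio tested), adjusted for the same demographics.

**Synthetic cohorts.** `atrophymap.synthetic` generates cohorts with an
ellipsoidal planted region whose 2-year mean change is exactly linear in
the predictor Z-score (known slope), smooth Gaussian noise, log-linear
time scaling (so the 2-year normalization is exact), and an exponential
proportional-hazards conversion process with known hazard ratios — so
every stage can be validated against ground truth.

## Worked example

The numbered drivers under `analysis/` run the full study on a
68-subject synthetic cohort (20³ grid, planted slope 0.01 log-J units
per predictor Z, true conversion HR 0.38 per Z) and write tables under
`results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/03_cluster_inference.py
python analysis/05_survival_models.py
python analysis/06_cohort_associations.py
```

prints, among other lines:

```
wrote cohort of 68 subjects to results/cohort
  converters: 12 / 68
1 suprathreshold clusters; critical size 10 voxels
significant clusters: [1] (corrected p ['0.0010'])
significant-region volume: 2.06 cm^3; Dice vs planted truth: 1.000
fornix_fa: HR 0.36 per Z (0.19-0.68), LR p = 0.0011 [true HR 0.38]
fsroi_logj: HR 0.43 per Z (0.24-0.79), LR p = 0.0055 [true HR indirect]
multi-regression of significant-region mean change: R^2 = 0.95 (n = 68)
  fornix_fa: p = 0.0000
```

Reading: the permutation test isolates one significant cluster that
coincides with the planted region (Dice 1.0, corrected p = 1/1001); the
Cox model recovers the planted hazard ratio (0.36 vs true 0.38); after
demographic adjustment the predictor remains the only significant term.
`analysis/02_compute_jacobians.py` demonstrates the displacement-field
entry point on an analytic warp, `04` the overlap/tissue-composition
reports, and `07` the calibration study below. The same stages are
scriptable via the `atrophymap` CLI (`simulate`, `jacobian`, `cluster`,
`overlap`, `associate`, `survive`, `run`, `show-config`).

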