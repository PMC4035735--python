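"""Synthetic longitudinal cohort generator with planted ground truth.

Emulates the statistical structure of a longitudinal tensor-based
morphometry study of cognitively normal elderly subjects:

* per-subject spatially smooth log-Jacobian change maps over the native
  interscan interval, with mildly negative background change (diffuse
  tissue loss) and Gaussian spatial noise;
* a planted ellipsoidal region whose 2-year-normalized mean change is
  exactly linear in a subject-level baseline predictor (a simulated
  fornix fractional-anisotropy value), with known slope ``effect_beta``;
* log-linear change over time, so the ``2.0 / dT`` normalization of the
  :mod:`~atrophymap.jacobian` module is exact by construction;
* a conversion-to-impairment process following a proportional-hazards
  model with specified hazard ratios per Z-unit of the brain factors,
  censored at a fixed follow-up horizon.

All randomness flows from the single integer ``seed`` through one
:class:`numpy.random.Generator`, so a spec generates byte-identical
cohorts on every run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .jacobian import DisplacementField, LogJacobianMap, write_log_jacobian

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: documented subject-table columns produced by :func:`generate_cohort`
SUBJECT_COLUMNS = [
    "id", "age", "gender", "education", "ethnicity",
    "delta_t_years", "fornix_fa", "fornix_fa_z", "converted", "time_years",
]


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates: center and radii."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(grid_shape, dtype=float)
        q = sum(
            ((idx[k] - self.center[k]) / self.radii[k]) ** 2 for k in range(3)
        )
        return q <= 1.0


@dataclass
class Demographics:
    """Distributions for the simulated demographic covariates.

    Defaults approximate a community-recruited elderly normal cohort:
    age ~ 73 +/- 7 years, ~73% female, ~11.4 +/- 4.8 years of education,
    two ethnicity levels (the smallest case exercising categorical
    encoding; add levels via ``ethnicity_probs``).
    """

    age_mean: float = 73.0
    age_sd: float = 7.0
    p_female: float = 0.73
    education_mean: float = 11.4
    education_sd: float = 4.8
    ethnicity_probs: dict[str, float] = field(
        default_factory=lambda: {"White": 0.45, "Hispanic": 0.55}
    )


@dataclass
class CohortSpec:
    """Full specification of a synthetic cohort.

    ``effect_beta`` is in log-Jacobian units (2-year scale) per unit
    predictor Z-score inside the planted region; ``noise_sigma`` is the
    voxelwise standard deviation of the white noise *before* Gaussian
    smoothing at ``smooth_fwhm_mm`` (smoothing shrinks the marginal SD).
    ``bg_mean`` is the 2-year background log-Jacobian everywhere
    (negative: diffuse tissue loss).  ``hr_per_z`` maps brain-factor
    names to true hazard ratios per Z-unit in the conversion model;
    ``fornix_fa`` refers to the planted predictor, any other name gets an
    independent standard-normal factor recorded in the subject table.
    """

    n_subjects: int = 68
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0
    effect_beta: float = 0.02
    planted_region: Ellipsoid = field(
        default_factory=lambda: Ellipsoid(center=(12.0, 12.0, 12.0), radii=(5.0, 5.0, 5.0))
    )
    bg_mean: float = -0.02
    noise_sigma: float = 0.05
    smooth_fwhm_mm: float = 6.0
    delta_t_range: tuple[float, float] = (1.0, 3.0)
    predictor_mean: float = 0.35
    predictor_sd: float = 0.05
    hr_per_z: dict[str, float] = field(default_factory=lambda: {"fornix_fa": 0.38})
    baseline_hazard: float = 0.04
    censor_time: float = 5.0
    demographics: Demographics = field(default_factory=Demographics)

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ConfigurationError(f"n_subjects must be >= 4, got {self.n_subjects}")
        if len(self.grid_shape) != 3 or any(int(s) < 2 for s in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be 3 ints >= 2, got {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ConfigurationError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        if any(r <= 0 for r in self.planted_region.radii):
            raise ConfigurationError(
                f"planted_region radii must be positive, got {self.planted_region.radii}"
            )
        for k in range(3):
            c, r = self.planted_region.center[k], self.planted_region.radii[k]
            if c - r < 0 or c + r > self.grid_shape[k] - 1:
                raise ConfigurationError(
                    "planted_region must fit inside grid_shape "
                    f"(axis {k}: center {c}, radius {r}, extent {self.grid_shape[k]})"
                )
        if not self.delta_t_range[0] > 0 or self.delta_t_range[1] < self.delta_t_range[0]:
            raise ConfigurationError(
                f"delta_t_range must be a positive interval, got {self.delta_t_range}"
            )
        if self.noise_sigma < 0:
            raise ConfigurationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.predictor_sd <= 0:
            raise ConfigurationError(f"predictor_sd must be > 0, got {self.predictor_sd}")
        if any(hr <= 0 for hr in self.hr_per_z.values()):
            raise ConfigurationError(f"hr_per_z values must be > 0, got {self.hr_per_z}")
        if self.baseline_hazard <= 0:
            raise ConfigurationError(f"baseline_hazard must be > 0, got {self.baseline_hazard}")
        if self.censor_time <= 0:
            raise ConfigurationError(f"censor_time must be > 0, got {self.censor_time}")


@dataclass
class SyntheticCohort:
    """Generated cohort: subject table, native-interval maps, ground truth."""

    subject_table: pd.DataFrame
    logj_maps: list[LogJacobianMap]
    truth_mask: np.ndarray
    effect_beta: float
    hr_per_z: dict[str, float]
    seed: int
    spec: CohortSpec

    @property
    def n_subjects(self) -> int:
        return len(self.subject_table)


def _smooth_noise(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    """White Gaussian noise smoothed to the requested FWHM (in mm)."""
    white = rng.normal(0.0, spec.noise_sigma, size=spec.grid_shape)
    if spec.smooth_fwhm_mm <= 0 or spec.noise_sigma == 0:
        return white
    sigma_vox = [
        spec.smooth_fwhm_mm * FWHM_TO_SIGMA / v for v in spec.voxel_size_mm
    ]
    return gaussian_filter(white, sigma=sigma_vox, mode="nearest")


def _simulate_conversion(
    rng: np.random.Generator,
    spec: CohortSpec,
    z_factors: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times under log-hazard = log(h0) + sum log(HR_f) z_f."""
    n = spec.n_subjects
    log_hazard = np.full(n, np.log(spec.baseline_hazard))
    for name, hr in spec.hr_per_z.items():
        log_hazard += np.log(hr) * z_factors[name]
    t_event = rng.exponential(1.0 / np.exp(log_hazard))
    converted = (t_event <= spec.censor_time).astype(int)
    time_years = np.minimum(t_event, spec.censor_time)
    return converted, time_years


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a synthetic cohort with a planted predictor-change association.

    For subject *i* with predictor Z-score ``z_i`` and interval ``dT_i``
    the native-interval map is::

        logJ_i = (dT_i / 2) * (bg_mean + effect_beta * z_i * region + noise_i)

    so after 2-year normalization the planted-region mean is linear in
    ``z_i`` with slope exactly ``effect_beta``.  Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    dem = spec.demographics

    fa = rng.normal(spec.predictor_mean, spec.predictor_sd, size=n)
    z = (fa - spec.predictor_mean) / spec.predictor_sd
    delta_t = rng.uniform(*spec.delta_t_range, size=n)

    age = rng.normal(dem.age_mean, dem.age_sd, size=n)
    gender = rng.binomial(1, dem.p_female, size=n)  # 1 = female
    education = np.clip(
        np.round(rng.normal(dem.education_mean, dem.education_sd, size=n)), 0, None
    )
    levels = list(dem.ethnicity_probs)
    probs = np.array([dem.ethnicity_probs[k] for k in levels], dtype=float)
    ethnicity = rng.choice(levels, size=n, p=probs / probs.sum())

    z_factors = {"fornix_fa": z}
    extra_cols: dict[str, np.ndarray] = {}
    for name in spec.hr_per_z:
        if name not in z_factors:
            z_factors[name] = rng.standard_normal(n)
            extra_cols[name] = z_factors[name]
    converted, time_years = _simulate_conversion(rng, spec, z_factors)

    region = spec.planted_region.mask(spec.grid_shape).astype(float)
    maps = []
    for i in range(n):
        two_year = (
            spec.bg_mean
            + spec.effect_beta * z[i] * region
            + _smooth_noise(rng, spec)
        )
        maps.append(
            LogJacobianMap(
                values=two_year * (delta_t[i] / 2.0),
                interval_years=float(delta_t[i]),
            )
        )

    table = pd.DataFrame(
        {
            "id": [f"sub-{i:03d}" for i in range(n)],
            "age": age,
            "gender": gender,
            "education": education,
            "ethnicity": ethnicity,
            "delta_t_years": delta_t,
            "fornix_fa": fa,
            "fornix_fa_z": z,
            "converted": converted,
            "time_years": time_years,
            **extra_cols,
        }
    )
    return SyntheticCohort(
        subject_table=table,
        logj_maps=maps,
        truth_mask=region.astype(bool),
        effect_beta=spec.effect_beta,
        hr_per_z=dict(spec.hr_per_z),
        seed=spec.seed,
        spec=spec,
    )


def generate_null_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Cohort with no planted effect: ``effect_beta = 0`` and all hazard
    ratios forced to 1 (the predictor still varies across subjects).

    The calibration fixture for the permutation test: any detected
    cluster is a false positive.
    """
    null_spec = dataclasses.replace(
        spec,
        effect_beta=0.0,
        hr_per_z={k: 1.0 for k in spec.hr_per_z},
    )
    cohort = generate_cohort(null_spec)
    cohort.effect_beta = 0.0
    return cohort


def scaling_displacement_field(
    grid_shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float],
    scale: float,
) -> DisplacementField:
    """Analytic uniform-scaling warp ``u(x) = (s - 1) x`` about the grid center.

    The Jacobian determinant is exactly ``s**3`` at every voxel, giving a
    closed-form end-to-end check of the finite-difference pipeline.
    """
    coords = np.stack(
        np.meshgrid(
            *[np.arange(s) * v for s, v in zip(grid_shape, voxel_size_mm)],
            indexing="ij",
        ),
        axis=-1,
    )
    center = coords.reshape(-1, 3).mean(axis=0)
    u = (scale - 1.0) * (coords - center)
    return DisplacementField(u=u, voxel_size_mm=voxel_size_mm)


# ---------------------------------------------------------------------------
# on-disk layout


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write a cohort to disk: per-subject NIfTI maps, subjects.csv,
    truth mask, and a JSON sidecar recording the generating spec."""
    out_dir = Path(out_dir)
    (out_dir / "maps").mkdir(parents=True, exist_ok=True)
    for sid, m in zip(cohort.subject_table["id"], cohort.logj_maps):
        write_log_jacobian(m, out_dir / "maps" / f"{sid}_logj.nii.gz")
    cohort.subject_table.to_csv(out_dir / "subjects.csv", index=False)
    nib.save(
        nib.Nifti1Image(cohort.truth_mask.astype(np.uint8), np.eye(4)),
        str(out_dir / "truth_mask.nii.gz"),
    )
    spec_dict = dataclasses.asdict(cohort.spec)
    spec_dict["planted_region"] = dataclasses.asdict(cohort.spec.planted_region)
    sidecar = {"spec": spec_dict, "seed": cohort.seed, "effect_beta": cohort.effect_beta}
    (out_dir / "cohort.json").write_text(json.dumps(sidecar, indent=2, default=list))
    return out_dir
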