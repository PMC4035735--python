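"""Cohort-level computational experiments.

Repeatable studies built from the library stages: familywise-error
calibration of the cluster-extent permutation test on null cohorts,
planted-region recovery on effect cohorts, and confidence-interval
coverage of the Cox conversion model.  These are the computations the
numbered analysis drivers narrate and the acceptance checks re-run.

Seeding: every experiment takes one base seed; per-replicate seeds are
spawned from it through :class:`numpy.random.SeedSequence` (folded below
2**31), so an experiment is a pure function of its arguments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .jacobian import normalize_to_two_years
from .survival import fit_cox
from .synthetic import (
    CohortSpec,
    Ellipsoid,
    generate_cohort,
    generate_null_cohort,
)
from .voxel_inference import (
    label_clusters,
    permutation_null,
    significant_clusters,
    voxelwise_slope_t,
)


def spawn_seeds(base_seed: int, n: int) -> list[int]:
    """n child seeds derived deterministically from one base seed."""
    return [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(base_seed).spawn(n)
    ]


def calibration_cohort_spec(n_subjects: int = 40, grid: int = 20) -> CohortSpec:
    """Cohort conditions for the permutation-calibration study: modest
    cohort on a compact grid with the generator's default noise field."""
    return CohortSpec(
        n_subjects=n_subjects,
        grid_shape=(grid, grid, grid),
        planted_region=Ellipsoid(
            center=(grid / 2.0,) * 3, radii=(grid / 5.0,) * 3
        ),
        seed=0,
    )


@dataclass
class CalibrationResult:
    n_cohorts: int
    n_detections: int
    detection_fraction: float
    critical_sizes: list[int]


def familywise_error_rate(
    base_seed: int,
    n_cohorts: int = 200,
    spec: CohortSpec | None = None,
    t_threshold: float = 3.5,
    connectivity: int = 26,
    n_perm: int = 500,
    alpha: float = 0.05,
) -> CalibrationResult:
    """Fraction of independent null cohorts in which at least one cluster
    is declared significant — the empirical familywise error rate of the
    max-cluster-size procedure, to be compared against ``alpha``.
    """
    spec = calibration_cohort_spec() if spec is None else spec
    seeds = spawn_seeds(base_seed, 2 * n_cohorts)
    detections = 0
    criticals = []
    for i in range(n_cohorts):
        cohort = generate_null_cohort(dataclasses.replace(spec, seed=seeds[2 * i]))
        maps = [normalize_to_two_years(m) for m in cohort.logj_maps]
        predictor = cohort.subject_table["fornix_fa"].to_numpy()
        mask = np.ones(spec.grid_shape, dtype=bool)
        tmap = voxelwise_slope_t(maps, predictor, mask)
        clusters = label_clusters(tmap, t_threshold, connectivity)
        null = permutation_null(
            maps, predictor, mask,
            t_threshold=t_threshold, connectivity=connectivity,
            n_perm=n_perm, seed=seeds[2 * i + 1],
            percentile=100.0 * (1.0 - alpha),
        )
        sig = significant_clusters(clusters, null, alpha)
        detections += bool(sig.cluster_labels)
        criticals.append(null.critical_size)
    return CalibrationResult(
        n_cohorts=n_cohorts,
        n_detections=detections,
        detection_fraction=detections / n_cohorts,
        critical_sizes=criticals,
    )


def snr_matched_effect_spec(
    n_subjects: int = 60, grid: int = 20, seed: int = 0
) -> CohortSpec:
    """Effect cohort whose planted slope equals the smoothed noise SD at a
    voxel (per-subject SNR ~ 1), derived from the generator's own impulse
    response rather than fixed by hand."""
    from scipy.ndimage import gaussian_filter

    spec = calibration_cohort_spec(n_subjects=n_subjects, grid=grid)
    delta = np.zeros(spec.grid_shape)
    delta[tuple(s // 2 for s in spec.grid_shape)] = 1.0
    sigma = [
        spec.smooth_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
        for v in spec.voxel_size_mm
    ]
    kernel = gaussian_filter(delta, sigma=sigma, mode="nearest")
    smoothed_sd = spec.noise_sigma * float(np.sqrt((kernel**2).sum()))
    return dataclasses.replace(spec, effect_beta=smoothed_sd, seed=seed)


def planted_recovery_dice(
    base_seed: int,
    n_seeds: int = 10,
    n_perm: int = 500,
    t_threshold: float = 3.5,
    connectivity: int = 26,
    alpha: float = 0.05,
) -> list[float]:
    """Dice overlap of the recovered significant mask with the planted
    truth region, across independently seeded effect cohorts."""
    seeds = spawn_seeds(base_seed, 2 * n_seeds)
    dices = []
    for i in range(n_seeds):
        spec = snr_matched_effect_spec(seed=seeds[2 * i])
        cohort = generate_cohort(spec)
        maps = [normalize_to_two_years(m) for m in cohort.logj_maps]
        predictor = cohort.subject_table["fornix_fa"].to_numpy()
        mask = np.ones(spec.grid_shape, dtype=bool)
        tmap = voxelwise_slope_t(maps, predictor, mask)
        clusters = label_clusters(tmap, t_threshold, connectivity)
        null = permutation_null(
            maps, predictor, mask,
            t_threshold=t_threshold, connectivity=connectivity,
            n_perm=n_perm, seed=seeds[2 * i + 1],
        )
        sig = significant_clusters(clusters, null, alpha)
        truth = cohort.truth_mask
        denom = sig.mask.sum() + truth.sum()
        dices.append(2.0 * (sig.mask & truth).sum() / denom if denom else 0.0)
    return dices


@dataclass
class CoverageResult:
    n_replicates: int
    n_covered: int
    coverage: float
    hazard_ratios: list[float]


def cox_ci_coverage(
    base_seed: int,
    n_replicates: int = 100,
    true_hr: float = 0.5,
    n_subjects: int = 500,
) -> CoverageResult:
    """95% Wald CI coverage of the true brain-factor hazard ratio across
    simulated cohorts (effectively uncensored)."""
    seeds = spawn_seeds(base_seed, n_replicates)
    covered = 0
    hrs = []
    for s in seeds:
        spec = CohortSpec(
            n_subjects=n_subjects,
            grid_shape=(6, 6, 6),
            planted_region=Ellipsoid((3.0, 3.0, 3.0), (1.5, 1.5, 1.5)),
            hr_per_z={"fornix_fa": true_hr},
            baseline_hazard=0.1,
            censor_time=1e6,
            seed=s,
        )
        fit = fit_cox(generate_cohort(spec).subject_table, "fornix_fa")
        lo, hi = fit.hazard_ratio_ci
        covered += lo <= true_hr <= hi
        hrs.append(fit.hazard_ratio)
    return CoverageResult(
        n_replicates=n_replicates,
        n_covered=covered,
        coverage=covered / n_replicates,
        hazard_ratios=hrs,
    )
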