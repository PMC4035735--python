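"""End-to-end pipeline: simulate -> normalize -> cluster -> summarize.

Runs the full analysis on a synthetic cohort (or a cohort previously
written to disk): 2-year normalization of the per-subject log-Jacobian
maps, voxelwise slope-t regression on the baseline predictor,
cluster-extent permutation inference, extraction of the significant
region, per-subject mean change in that region as a derived brain
factor, then the cohort-level models — multiple regression with
demographic adjustment, factor correlation matrix, and Cox
proportional-hazards conversion models.

Every stage writes its outputs with a JSON provenance sidecar (stage
name, inputs, seed, package version) so any stage can be re-run from its
written intermediates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .cohort_models import correlation_matrix, fit_multi_regression
from .errors import ConfigurationError
from .jacobian import normalize_to_two_years
from .roi_stats import ROIMask, overlap_composition, roi_mean
from .survival import fit_cox
from .synthetic import CohortSpec, SyntheticCohort, generate_cohort, write_cohort
from .voxel_inference import (
    label_clusters,
    permutation_null,
    significant_clusters,
    voxelwise_slope_t,
)

log = logging.getLogger("atrophymap")


@dataclass
class PipelineConfig:
    """Settings of the full pipeline; defaults match the printed analysis
    settings (t > 3.5, 1000 permutations, 95th percentile, alpha 0.05)."""

    out_dir: str = "pipeline_out"
    predictor_col: str = "fornix_fa"
    t_threshold: float = 3.5
    n_perm: int = 1000
    alpha: float = 0.05
    connectivity: int = 26
    seed: int = 0
    clamp_eps: float = 1e-6
    target_interval_years: float = 2.0
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)

    def validate(self) -> None:
        if self.n_perm < 100:
            raise ConfigurationError(f"n_perm must be >= 100, got {self.n_perm}")
        if not 0 < self.alpha <= 0.5:
            raise ConfigurationError(f"alpha must be in (0, 0.5], got {self.alpha}")
        if self.connectivity not in (6, 18, 26):
            raise ConfigurationError(f"connectivity must be 6/18/26, got {self.connectivity}")
        if self.target_interval_years != 2.0:
            raise ConfigurationError(
                "target_interval_years other than 2.0 is not supported"
            )
        self.cohort_spec.validate()


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: SyntheticCohort
    tmap: object
    clusters: object
    null: object
    significant: object
    report: dict


def _sidecar(path: Path, stage: str, inputs: dict, seed: int) -> None:
    meta = {"stage": stage, "inputs": inputs, "seed": seed, "version": __version__}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2, default=str))


def run_pipeline(
    config: PipelineConfig, cohort: SyntheticCohort | None = None
) -> PipelineResult:
    """Execute all stages in order and write the report bundle.

    ``cohort`` may be supplied directly (e.g. a pre-generated null
    cohort); otherwise one is generated from ``config.cohort_spec``.
    Any stage failure aborts with the stage name in the exception.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"settings": {
        "t_threshold": config.t_threshold, "n_perm": config.n_perm,
        "alpha": config.alpha, "connectivity": config.connectivity,
        "seed": config.seed,
    }}

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        return t0

    def done(name, t0):
        log.info("stage %s: %.2fs", name, time.perf_counter() - t0)

    # -- simulate -----------------------------------------------------------
    t0 = stage("simulate")
    if cohort is None:
        cohort = generate_cohort(config.cohort_spec)
    write_cohort(cohort, out / "cohort")
    table = cohort.subject_table
    done("simulate", t0)

    # -- normalize ----------------------------------------------------------
    t0 = stage("normalize")
    normalized = [normalize_to_two_years(m) for m in cohort.logj_maps]
    done("normalize", t0)

    spec = cohort.spec
    voxel_volume_cm3 = float(np.prod(spec.voxel_size_mm)) / 1000.0
    mask = np.ones(spec.grid_shape, dtype=bool)
    predictor = table[config.predictor_col].to_numpy(dtype=float)

    # -- cluster inference ---------------------------------------------------
    t0 = stage("cluster")
    tmap = voxelwise_slope_t(normalized, predictor, mask)
    clusters = label_clusters(
        tmap, config.t_threshold, config.connectivity, voxel_volume_cm3
    )
    null = permutation_null(
        normalized, predictor, mask,
        t_threshold=config.t_threshold, connectivity=config.connectivity,
        n_perm=config.n_perm, seed=config.seed,
    )
    sig = significant_clusters(clusters, null, config.alpha, voxel_volume_cm3)
    nib.save(nib.Nifti1Image(tmap.values.astype(np.float32), np.eye(4)),
             str(out / "tmap.nii.gz"))
    nib.save(nib.Nifti1Image(clusters.label_map.astype(np.int32), np.eye(4)),
             str(out / "clusters.nii.gz"))
    nib.save(nib.Nifti1Image(sig.mask.astype(np.uint8), np.eye(4)),
             str(out / "significant_mask.nii.gz"))
    for f in ("tmap.nii.gz", "clusters.nii.gz", "significant_mask.nii.gz"):
        _sidecar(out / f, "cluster", {"predictor": config.predictor_col}, config.seed)
    cluster_table = pd.DataFrame(
        {
            "label": np.arange(1, clusters.n_clusters + 1),
            "size_voxels": clusters.sizes,
            "volume_cm3": clusters.volumes_cm3,
            "significant": [
                lab in sig.cluster_labels for lab in range(1, clusters.n_clusters + 1)
            ],
        }
    )
    cluster_table.to_csv(out / "clusters.csv", index=False)
    report["clusters"] = {
        "n_clusters": clusters.n_clusters,
        "critical_size": null.critical_size,
        "significant_labels": sig.cluster_labels,
        "corrected_p": sig.corrected_p,
        "significant_volume_cm3": sig.total_volume_cm3,
    }
    done("cluster", t0)

    # -- overlap with truth --------------------------------------------------
    t0 = stage("overlap")
    truth_roi = ROIMask("planted_region", cohort.truth_mask, voxel_volume_cm3)
    overlap = overlap_composition(sig.mask, [truth_roi], "significant_mask")
    overlap.to_csv(out / "overlap.csv", index=False)
    _sidecar(out / "overlap.csv", "overlap", {"reference": "significant_mask"}, config.seed)
    report["overlap"] = overlap.to_dict(orient="records")
    done("overlap", t0)

    # -- derived brain factor: mean change in the significant region --------
    region_for_factor = sig.mask if sig.mask.any() else cohort.truth_mask
    factor_roi = ROIMask("significant_region", region_for_factor, voxel_volume_cm3)
    table = table.copy()
    table["fsroi_logj"] = [roi_mean(m.values, factor_roi) for m in normalized]
    report["fsroi_factor_from"] = (
        "significant_mask" if sig.mask.any() else "truth_mask (no significant cluster)"
    )

    # -- cohort models -------------------------------------------------------
    t0 = stage("associate")
    terms = table[["age", "gender", "education", "ethnicity", config.predictor_col]]
    reg = fit_multi_regression(table["fsroi_logj"], terms)
    report["multi_regression"] = {
        "r_squared": reg.r_squared,
        "p_values": {k: float(v) for k, v in reg.p_values.items()},
        "n": reg.n,
    }
    corr = correlation_matrix(table[["fsroi_logj", config.predictor_col]])
    corr.to_csv(out / "correlation_matrix.csv")
    _sidecar(out / "correlation_matrix.csv", "associate", {}, config.seed)
    report["correlation_matrix"] = corr.to_dict()
    done("associate", t0)

    # -- survival ------------------------------------------------------------
    t0 = stage("survive")
    survival_rows = []
    for factor in (config.predictor_col, "fsroi_logj"):
        fit = fit_cox(table, factor)
        lo, hi = fit.hazard_ratio_ci
        survival_rows.append(
            {
                "brain_factor": factor,
                "hazard_ratio_per_z": fit.hazard_ratio,
                "hr_ci_lower": lo,
                "hr_ci_upper": hi,
                "lr_p_value": fit.lr_p_value,
                "n": fit.n,
                "n_events": fit.n_events,
            }
        )
    survival_table = pd.DataFrame(survival_rows)
    survival_table.to_csv(out / "survival.csv", index=False)
    _sidecar(out / "survival.csv", "survive", {}, config.seed)
    report["survival"] = survival_rows
    done("survive", t0)

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return PipelineResult(
        config=config, cohort=cohort, tmap=tmap, clusters=clusters,
        null=null, significant=sig, report=report,
    )


def default_config_dict() -> dict:
    """All pipeline defaults as a plain dict (for --show-config)."""
    cfg = PipelineConfig()
    d = dataclasses.asdict(cfg)
    return d
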