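"""Demographic-adjusted association and factor correlations.

Multiple regression of the significant-region mean change on fornix FA
plus age, gender, education, and ethnicity (does the voxelwise
association survive adjustment?), and the Pearson correlation matrix of
the brain factors.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import ALPHA, CONNECTIVITY, N_PERM, PERM_SEED, RESULTS, STUDY_SPEC, T_THRESHOLD

from atrophymap.cohort_models import correlation_matrix, fit_multi_regression
from atrophymap.jacobian import normalize_to_two_years
from atrophymap.roi_stats import ROIMask, roi_mean
from atrophymap.synthetic import generate_cohort
from atrophymap.voxel_inference import (
    label_clusters,
    permutation_null,
    significant_clusters,
    voxelwise_slope_t,
)


def main() -> None:
    out = RESULTS / "associations"
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(STUDY_SPEC)
    maps = [normalize_to_two_years(m) for m in cohort.logj_maps]
    predictor = cohort.subject_table["fornix_fa"].to_numpy()
    mask = np.ones(STUDY_SPEC.grid_shape, bool)
    tmap = voxelwise_slope_t(maps, predictor, mask)
    clusters = label_clusters(tmap, T_THRESHOLD, CONNECTIVITY)
    null = permutation_null(
        maps, predictor, mask, T_THRESHOLD, CONNECTIVITY, N_PERM, PERM_SEED
    )
    sig = significant_clusters(clusters, null, ALPHA)
    region = sig.mask if sig.mask.any() else cohort.truth_mask

    table = cohort.subject_table.copy()
    roi = ROIMask("significant_region", region)
    table["fsroi_logj"] = [roi_mean(m.values, roi) for m in maps]

    terms = table[["age", "gender", "education", "ethnicity", "fornix_fa"]]
    fit = fit_multi_regression(table["fsroi_logj"], terms)
    print(f"multi-regression of significant-region mean change: "
          f"R^2 = {fit.r_squared:.2f} (n = {fit.n})")
    for term in fit.p_values.index:
        if term != "const":
            print(f"  {term}: p = {fit.p_values[term]:.4f}")
    pd.DataFrame(
        {"coefficient": fit.coefficients, "p_value": fit.p_values}
    ).to_csv(out / "multi_regression.csv")

    corr = correlation_matrix(table[["fsroi_logj", "fornix_fa", "age"]])
    corr.to_csv(out / "correlation_matrix.csv")
    print("factor correlation matrix:")
    print(corr.round(2).to_string())


if __name__ == "__main__":
    main()
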