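"""Composition of the significant region: ROI overlaps and tissue classes.

Re-derives the significant mask on the study cohort, then reports what
fraction of each reference ROI it covers and its white/gray/CSF
composition against a synthetic tissue segmentation (a white-matter core
containing the planted region, a gray-matter shell, CSF elsewhere).
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import ALPHA, CONNECTIVITY, N_PERM, PERM_SEED, RESULTS, STUDY_SPEC, T_THRESHOLD

from atrophymap.jacobian import normalize_to_two_years
from atrophymap.roi_stats import ROIMask, overlap_composition, tissue_composition
from atrophymap.synthetic import Ellipsoid, generate_cohort
from atrophymap.voxel_inference import (
    label_clusters,
    permutation_null,
    significant_clusters,
    voxelwise_slope_t,
)


def synthetic_segmentation(grid_shape):
    """Labeled volume: WM core (3) containing the planted region, a GM
    shell (2) around it, CSF (1) elsewhere."""
    wm = Ellipsoid((10.0, 10.0, 10.0), (6.0, 6.0, 6.0)).mask(grid_shape)
    gm = Ellipsoid((10.0, 10.0, 10.0), (8.5, 8.5, 8.5)).mask(grid_shape) & ~wm
    seg = np.ones(grid_shape, dtype=int)
    seg[gm] = 2
    seg[wm] = 3
    return seg


def main() -> None:
    out = RESULTS / "overlap"
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

    rois = [
        ROIMask("planted_region", cohort.truth_mask),
        ROIMask("planted_core", Ellipsoid((10.0,) * 3, (2.0,) * 3).mask(STUDY_SPEC.grid_shape)),
        ROIMask("off_target", Ellipsoid((5.0, 5.0, 15.0), (2.5, 2.5, 2.5)).mask(STUDY_SPEC.grid_shape)),
    ]
    overlap = overlap_composition(sig.mask, rois, "significant_mask")
    overlap.to_csv(out / "overlap.csv", index=False)
    print(overlap[["roi_name", "pct_of_roi"]].to_string(index=False))

    seg = synthetic_segmentation(STUDY_SPEC.grid_shape)
    comp = tissue_composition(sig.mask, seg, {"CSF": 1, "GM": 2, "WM": 3})
    print("tissue composition of significant region: "
          + ", ".join(f"{k} {100 * v:.1f}%" for k, v in comp.items()))


if __name__ == "__main__":
    main()
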