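"""ROI summaries and composition of a significant-association mask.

Covers the measurement side of the analysis: mean of a scalar image over
an ROI (e.g. mean FA of a white-matter tract), the percentage of each
atlas ROI covered by a reference mask (the "% of ROI" overlap table),
and the tissue-class composition of a mask against a labeled
segmentation (e.g. ~80% white / ~20% gray matter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class ROIMask:
    name: str
    mask: np.ndarray
    voxel_volume_cm3: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def roi_mean(image: np.ndarray, roi: ROIMask) -> float:
    """Arithmetic mean of ``image`` over the ROI voxels."""
    image = np.asarray(image, dtype=float)
    if image.shape != roi.mask.shape:
        raise DataError(
            f"image grid {image.shape} does not match ROI grid {roi.mask.shape}"
        )
    if not roi.mask.any():
        raise DataError(f"ROI {roi.name!r} is empty")
    return float(image[roi.mask].mean())


def overlap_composition(
    reference: np.ndarray,
    rois: list[ROIMask],
    reference_name: str = "reference",
) -> pd.DataFrame:
    """Per-ROI overlap percentages against a reference mask.

    ``pct_of_roi`` = 100 * |roi & reference| / |roi| (the denominator is
    the atlas ROI); ``pct_of_reference`` is the converse share, emitted
    for completeness.  Empty ROIs are flagged in the ``note`` column
    rather than dropped.  Percentages are not rounded here.
    """
    reference = np.asarray(reference, dtype=bool)
    rows = []
    for roi in rois:
        if roi.mask.shape != reference.shape:
            raise DataError(
                f"ROI {roi.name!r} grid {roi.mask.shape} does not match "
                f"reference grid {reference.shape}"
            )
        n_roi = int(roi.mask.sum())
        n_inter = int((roi.mask & reference).sum())
        n_ref = int(reference.sum())
        rows.append(
            {
                "roi_name": roi.name,
                "pct_of_roi": 100.0 * n_inter / n_roi if n_roi else np.nan,
                "pct_of_reference": 100.0 * n_inter / n_ref if n_ref else np.nan,
                "roi_voxels": n_roi,
                "intersection_voxels": n_inter,
                "reference_mask_name": reference_name,
                "note": "" if n_roi else "empty ROI",
            }
        )
    return pd.DataFrame(rows)


def tissue_composition(
    reference: np.ndarray,
    segmentation: np.ndarray,
    class_labels: dict[str, int],
) -> dict[str, float]:
    """Fraction of reference-mask voxels per tissue class.

    ``class_labels`` maps class names (e.g. WM/GM/CSF) to integer labels
    of the segmentation.  Voxels carrying labels not listed are counted
    under ``"unclassified"``; fractions sum to 1 over classified +
    unclassified.
    """
    reference = np.asarray(reference, dtype=bool)
    segmentation = np.asarray(segmentation)
    if segmentation.shape != reference.shape:
        raise DataError("segmentation grid does not match reference grid")
    n_ref = int(reference.sum())
    if n_ref == 0:
        raise DataError("reference mask is empty")
    labels_in_ref = segmentation[reference]
    out: dict[str, float] = {}
    classified = 0
    for name, lab in class_labels.items():
        n = int((labels_in_ref == lab).sum())
        out[name] = n / n_ref
        classified += n
    out["unclassified"] = (n_ref - classified) / n_ref
    return out
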