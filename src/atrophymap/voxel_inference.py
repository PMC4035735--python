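"""Mass-univariate regression and cluster-extent permutation inference.

At every voxel inside an analysis mask, the 2-year-normalized
log-Jacobian values across subjects are regressed on a single scalar
baseline predictor (ordinary least squares with intercept) and the
Student t statistic of the slope is recorded.  Suprathreshold voxels
(t above a fixed threshold, 3.5 by default elsewhere) are grouped into
connected clusters, and familywise inference on cluster extent follows
the maximal-statistic permutation scheme: the predictor vector is
permuted across subjects, the t-map and clusters recomputed, and the
maximum cluster size recorded per permutation.  Observed clusters larger
than the 95th percentile of that null distribution are declared
significant; their union is the significant-association region.

With a single regressor and an intercept, permuting the predictor is an
exact exchangeability scheme under the null of no association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DataError, StatisticsError, UsageError
from .jacobian import LogJacobianMap

#: cap substituted for infinite t at perfect-fit voxels
T_CAP = 1e6

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class TMap:
    """Voxelwise slope-t map of the single-predictor regression."""

    values: np.ndarray
    n_subjects: int
    mask: np.ndarray
    capped: np.ndarray | None = None  # perfect-fit voxels where t was capped


@dataclass
class ClusterSet:
    """Connected suprathreshold clusters of a t-map."""

    label_map: np.ndarray
    sizes: np.ndarray  # voxels, indexed by label-1
    volumes_cm3: np.ndarray
    t_threshold: float
    connectivity: int

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def max_size(self) -> int:
        return int(self.sizes.max()) if self.n_clusters else 0


@dataclass
class PermutationNull:
    """Null distribution of the per-permutation maximum cluster size."""

    max_cluster_sizes: np.ndarray
    n_perm: int
    seed: int
    critical_size: int
    t_threshold: float
    connectivity: int


@dataclass
class SignificantROI:
    """Union of clusters surviving the cluster-size criterion."""

    mask: np.ndarray
    cluster_labels: list[int]
    cluster_sizes: list[int]
    corrected_p: list[float]
    total_volume_cm3: float


def _as_stack(maps, mask: np.ndarray) -> np.ndarray:
    """Stack per-subject maps into (n_subjects, n_mask_voxels)."""
    rows = []
    for m in maps:
        values = m.values if isinstance(m, LogJacobianMap) else np.asarray(m, dtype=float)
        if isinstance(m, LogJacobianMap) and not m.is_normalized:
            raise UsageError("all maps must be normalized to the 2-year interval")
        if values.shape != mask.shape:
            raise DataError(
                f"map grid {values.shape} does not match mask grid {mask.shape}"
            )
        rows.append(values[mask])
    return np.asarray(rows, dtype=float)


def _t_from_moments(
    sxy: np.ndarray, sxx: float, syy: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Slope t from the centered cross-moments; sxy may be 1-D or
    (n_perm, n_voxels).  Constant voxels get t = 0; perfect fits are
    capped at +/-T_CAP and flagged."""
    denom2 = sxx * syy - sxy**2  # = sxx*syy*(1-r^2) >= 0 up to rounding
    with np.errstate(divide="ignore", invalid="ignore"):
        t = sxy * np.sqrt((n - 2) / np.maximum(denom2, 0.0))
    constant = np.broadcast_to(syy <= 0, t.shape)
    perfect = (~constant) & ~np.isfinite(t)
    t[constant] = 0.0
    t[perfect] = np.sign(sxy[perfect]) * T_CAP
    np.clip(t, -T_CAP, T_CAP, out=t)
    return t, perfect


def _slope_t_rows(data: np.ndarray, predictor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slope t-statistics for OLS of each column of ``data`` on ``predictor``.

    Uses the correlation form t = r sqrt(n-2) / sqrt(1-r^2),
    algebraically identical to slope / SE(slope) with n-2 df.
    """
    n = len(predictor)
    xc = predictor - predictor.mean()
    sxx = float(xc @ xc)
    yc = data - data.mean(axis=0)
    syy = np.einsum("ij,ij->j", yc, yc)
    sxy = xc @ yc
    return _t_from_moments(sxy, sxx, syy, n)


def voxelwise_slope_t(maps, predictor, mask) -> TMap:
    """OLS slope t-map of log-Jacobian change on a scalar predictor.

    Positive t means higher predictor values co-occur with less negative
    change (less tissue loss), the expected sign when the predictor is a
    white-matter integrity measure.
    """
    mask = np.asarray(mask, dtype=bool)
    predictor = np.asarray(predictor, dtype=float)
    n = len(predictor)
    if n < 4:
        raise StatisticsError(f"need >= 4 subjects for a slope t-test, got {n}")
    if len(maps) != n:
        raise DataError(f"{len(maps)} maps but {n} predictor values")
    if np.ptp(predictor) == 0:
        raise StatisticsError("predictor is constant; slope is not estimable")
    data = _as_stack(maps, mask)
    t_flat, capped_flat = _slope_t_rows(data, predictor)
    values = np.zeros(mask.shape)
    values[mask] = t_flat
    capped = np.zeros(mask.shape, dtype=bool)
    capped[mask] = capped_flat
    return TMap(values=values, n_subjects=n, mask=mask, capped=capped)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ConfigurationError(f"connectivity must be one of 6/18/26, got {connectivity}")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def label_clusters(
    tmap: TMap,
    t_threshold: float,
    connectivity: int = 26,
    voxel_volume_cm3: float = 1.0,
    two_sided: bool = False,
) -> ClusterSet:
    """Connected components of the suprathreshold set {t > threshold}.

    One-sided by default (only positive-t clusters, matching the
    direction of interest); ``two_sided=True`` thresholds |t| instead.
    """
    if not np.isfinite(t_threshold):
        raise ConfigurationError("t_threshold must be finite")
    stat = np.abs(tmap.values) if two_sided else tmap.values
    supra = (stat > t_threshold) & tmap.mask
    label_map, n_labels = ndimage.label(supra, structure=_structure(connectivity))
    sizes = (
        np.bincount(label_map[label_map > 0], minlength=n_labels + 1)[1:]
        if n_labels
        else np.zeros(0, dtype=int)
    )
    return ClusterSet(
        label_map=label_map,
        sizes=sizes.astype(int),
        volumes_cm3=sizes * voxel_volume_cm3,
        t_threshold=float(t_threshold),
        connectivity=connectivity,
    )


def _max_cluster_size(supra: np.ndarray, structure: np.ndarray) -> int:
    label_map, n_labels = ndimage.label(supra, structure=structure)
    if n_labels == 0:
        return 0
    return int(np.bincount(label_map[label_map > 0]).max())


def permutation_null(
    maps,
    predictor,
    mask,
    t_threshold: float = 3.5,
    connectivity: int = 26,
    n_perm: int = 1000,
    seed: int = 0,
    percentile: float = 95.0,
    two_sided: bool = False,
    pooled: bool = False,
) -> PermutationNull:
    """Max-cluster-size permutation null of the cluster-extent statistic.

    For each of ``n_perm`` permutations the predictor is shuffled across
    subjects (maps fixed), the t-map recomputed, clusters labeled, and
    the maximum cluster size recorded.  ``critical_size`` is the
    ceil(percentile/100 * n_perm)-th order statistic of those maxima;
    significance downstream requires a strictly larger observed cluster
    (conservative under ties).

    ``pooled=True`` switches the null statistic from the per-permutation
    maximum to the pooled collection of all null cluster sizes — a more
    liberal reading of a cluster-size percentile criterion, provided for
    comparison; the default max-statistic form controls familywise error.
    """
    if n_perm < 100:
        raise ConfigurationError(f"n_perm must be >= 100, got {n_perm}")
    if not 0 < percentile < 100:
        raise ConfigurationError(f"percentile must be in (0, 100), got {percentile}")
    mask = np.asarray(mask, dtype=bool)
    predictor = np.asarray(predictor, dtype=float)
    data = _as_stack(maps, mask)
    structure = _structure(connectivity)
    rng = np.random.default_rng(seed)

    # moments of the (fixed) maps are shared by all permutations, and sxx is
    # permutation invariant; each chunk of permuted t-maps is one BLAS matmul
    n = len(predictor)
    xc = predictor - predictor.mean()
    sxx = float(xc @ xc)
    yc = data - data.mean(axis=0)
    syy = np.einsum("ij,ij->j", yc, yc)

    supra_grid = np.zeros(mask.shape, dtype=bool)
    maxima = np.empty(n_perm, dtype=int)
    pooled_sizes: list[int] = []
    chunk = 128
    for start in range(0, n_perm, chunk):
        c = min(chunk, n_perm - start)
        P = np.stack([xc[rng.permutation(n)] for _ in range(c)])
        t_rows, _ = _t_from_moments(P @ yc, sxx, syy, n)
        if two_sided:
            np.abs(t_rows, out=t_rows)
        for row in t_rows:
            supra_grid[mask] = row > t_threshold
            if pooled:
                label_map, n_labels = ndimage.label(supra_grid, structure=structure)
                sizes = np.bincount(label_map[label_map > 0]) if n_labels else None
                if n_labels:
                    pooled_sizes.extend(int(s) for s in sizes[1:])
                maxima[start] = int(sizes.max()) if n_labels else 0
            else:
                maxima[start] = _max_cluster_size(supra_grid, structure)
            start += 1

    null_sizes = np.asarray(pooled_sizes if pooled else maxima, dtype=int)
    if pooled and len(null_sizes) == 0:
        null_sizes = np.zeros(1, dtype=int)
    order = np.sort(null_sizes)
    k = int(np.ceil(percentile / 100.0 * len(order)))
    critical = int(order[min(k, len(order)) - 1])
    return PermutationNull(
        max_cluster_sizes=maxima,
        n_perm=n_perm,
        seed=seed,
        critical_size=critical,
        t_threshold=float(t_threshold),
        connectivity=connectivity,
    )


def significant_clusters(
    observed: ClusterSet,
    null: PermutationNull,
    alpha: float = 0.05,
    voxel_volume_cm3: float = 1.0,
) -> SignificantROI:
    """Clusters whose extent exceeds the permutation critical size.

    Per-cluster familywise-corrected p-values use the standard
    permutation estimator ``(1 + #{null max >= size}) / (1 + n_perm)``.
    The union mask of retained clusters is the significant-association
    region (the analysis' region-of-interest output).
    """
    if not 0 < alpha <= 0.5:
        raise ConfigurationError(f"alpha must be in (0, 0.5], got {alpha}")
    if (observed.t_threshold, observed.connectivity) != (
        null.t_threshold,
        null.connectivity,
    ):
        raise UsageError(
            "observed clusters and permutation null were built with different "
            "threshold/connectivity settings"
        )
    null_max = np.sort(null.max_cluster_sizes)
    labels, sizes, pvals = [], [], []
    for lab, size in enumerate(observed.sizes, start=1):
        if size > null.critical_size:
            n_ge = len(null_max) - np.searchsorted(null_max, size, side="left")
            p = (1 + n_ge) / (1 + null.n_perm)
            labels.append(lab)
            sizes.append(int(size))
            pvals.append(float(p))
    mask = np.isin(observed.label_map, labels) if labels else np.zeros_like(
        observed.label_map, dtype=bool
    )
    return SignificantROI(
        mask=mask,
        cluster_labels=labels,
        cluster_sizes=sizes,
        corrected_p=pvals,
        total_volume_cm3=float(mask.sum() * voxel_volume_cm3),
    )
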