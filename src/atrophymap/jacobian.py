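"""Local volume change from longitudinal deformation fields.

Tensor-based morphometry quantifies longitudinal brain change by the
Jacobian determinant of the warp aligning a subject's baseline scan to
the follow-up scan.  With the warp stored as a displacement field
``x -> x + u(x)`` (u in mm on the image grid), the local volume-change
factor is ``det(I + Du)`` where ``Du`` is the 3x3 spatial derivative of
``u`` in physical (mm) units.  Determinants in (0, 1) mean shrinkage,
>1 expansion.  The natural log gives a change measure symmetric about 0
(negative = tissue contraction), the "log-Jacobian".

Because interscan intervals differ across subjects and tissue change is
roughly log-linear in time, maps are made comparable by scaling each
log-Jacobian image by ``2.0 / dT`` (dT = interscan interval in years),
i.e. normalizing every subject to a nominal 2-year change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, DataError, UsageError

#: sentinel value of :attr:`LogJacobianMap.interval_years` after normalization
NORMALIZED_2YR = "normalized-2yr"

#: default clamp for non-positive determinants before the log transform
DEFAULT_CLAMP_EPS = 1e-6


@dataclass
class DisplacementField:
    """Baseline-to-follow-up warp ``x -> x + u(x)`` on a regular grid.

    Parameters
    ----------
    u
        Array of shape ``(nx, ny, nz, 3)``; last axis is the displacement
        vector in mm, component order matching the grid axes.
    voxel_size_mm
        Physical voxel spacing along each grid axis, in mm.
    """

    u: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise DataError(
                f"displacement field must have shape (nx, ny, nz, 3), got {self.u.shape}"
            )
        if any(s < 2 for s in self.u.shape[:3]):
            raise DataError(
                "grid must extend at least 2 voxels along each axis for finite differences"
            )
        if not np.all(np.isfinite(self.u)):
            raise DataError("displacement field contains non-finite values")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ConfigurationError(f"voxel_size_mm must be 3 positive reals, got {vs}")
        self.voxel_size_mm = vs

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.u.shape[:3]


@dataclass
class LogJacobianMap:
    """Per-subject map of log proportional volume change.

    ``values`` are dimensionless: 0 = no change, negative = contraction,
    positive = expansion.  ``interval_years`` is the interscan interval
    the map measures change over, or :data:`NORMALIZED_2YR` once the map
    has been scaled to the common 2-year interval.  ``mask`` marks valid
    voxels; voxels whose determinant had to be clamped before the log
    are excluded from it.
    """

    values: np.ndarray
    interval_years: float | str
    mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DataError(f"log-Jacobian map must be 3-D, got shape {self.values.shape}")
        if isinstance(self.interval_years, str):
            if self.interval_years != NORMALIZED_2YR:
                raise ConfigurationError(
                    f"interval_years must be a positive number or {NORMALIZED_2YR!r}"
                )
        elif not self.interval_years > 0:
            raise ConfigurationError(f"interval_years must be > 0, got {self.interval_years}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise DataError("mask shape does not match values")

    @property
    def is_normalized(self) -> bool:
        return self.interval_years == NORMALIZED_2YR

    @property
    def n_clamped(self) -> int:
        return 0 if self.mask is None else int((~self.mask).sum())


def jacobian_determinant(fld: DisplacementField) -> np.ndarray:
    """Voxelwise ``det(I + Du)`` of the mapping ``x -> x + u(x)``.

    Derivatives use central differences at interior voxels and one-sided
    differences at grid boundaries, with spacing taken from
    ``fld.voxel_size_mm`` so anisotropic voxels are handled correctly.

    Returns a 3-D array of volume-change factors (1 = no change).
    """
    # Du[i, j] = d u_i / d x_j; np.gradient is central interior, one-sided at edges
    grads = [
        np.gradient(fld.u[..., i], *fld.voxel_size_mm, axis=(0, 1, 2))
        for i in range(3)
    ]
    J = np.empty(fld.grid_shape + (3, 3), dtype=float)
    for i in range(3):
        for j in range(3):
            J[..., i, j] = grads[i][j]
            if i == j:
                J[..., i, j] += 1.0
    # explicit 3x3 determinant: cheaper and exact vs np.linalg.det's LU
    a, b, c = J[..., 0, 0], J[..., 0, 1], J[..., 0, 2]
    d, e, f = J[..., 1, 0], J[..., 1, 1], J[..., 1, 2]
    g, h, i_ = J[..., 2, 0], J[..., 2, 1], J[..., 2, 2]
    return a * (e * i_ - f * h) - b * (d * i_ - f * g) + c * (d * h - e * g)


def log_jacobian(
    det_map: np.ndarray,
    interval_years: float,
    clamp_eps: float = DEFAULT_CLAMP_EPS,
    affine: np.ndarray | None = None,
) -> LogJacobianMap:
    """Log transform of a determinant map, clamping non-positive values.

    Determinants below ``clamp_eps`` (numerical folding at e.g. CSF
    boundaries) are clamped to ``clamp_eps`` before the log and excluded
    from the validity mask rather than aborting the run.
    """
    if clamp_eps <= 0:
        raise ConfigurationError(f"clamp_eps must be > 0, got {clamp_eps}")
    if not interval_years > 0:
        raise ConfigurationError(f"interval_years must be > 0, got {interval_years}")
    det_map = np.asarray(det_map, dtype=float)
    ok = det_map >= clamp_eps
    values = np.log(np.maximum(det_map, clamp_eps))
    return LogJacobianMap(
        values=values,
        interval_years=float(interval_years),
        mask=ok,
        affine=np.eye(4) if affine is None else affine,
    )


def normalize_to_two_years(m: LogJacobianMap) -> LogJacobianMap:
    """Scale a native-interval map by ``2.0 / dT`` to a nominal 2-year change.

    Valid under the log-linearity-in-time assumption.  Raises
    :class:`UsageError` if the map is already normalized.
    """
    if m.is_normalized:
        raise UsageError("map is already normalized to the 2-year interval")
    factor = 2.0 / float(m.interval_years)
    return LogJacobianMap(
        values=m.values * factor,
        interval_years=NORMALIZED_2YR,
        mask=None if m.mask is None else m.mask.copy(),
        affine=m.affine.copy(),
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_displacement_field(path: str | Path) -> DisplacementField:
    """Read a 4-D NIfTI displacement field (last axis = x,y,z component, mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise DataError(f"{path}: expected 4-D NIfTI with 3 vector components")
    zooms = img.header.get_zooms()[:3]
    return DisplacementField(u=data, voxel_size_mm=tuple(float(z) for z in zooms))


def write_log_jacobian(m: LogJacobianMap, path: str | Path) -> None:
    """Write a log-Jacobian map as 3-D NIfTI plus a JSON sidecar.

    The sidecar records the interval semantics and the clamp count so the
    map's provenance survives the round trip.
    """
    path = Path(path)
    nib.save(nib.Nifti1Image(m.values.astype(np.float32), m.affine), str(path))
    sidecar = {
        "interval_years": m.interval_years,
        "n_clamped": m.n_clamped,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_log_jacobian(path: str | Path) -> LogJacobianMap:
    """Read a log-Jacobian map written by :func:`write_log_jacobian`."""
    path = Path(path)
    img = nib.load(str(path))
    sidecar_path = path.with_suffix("").with_suffix(".json")
    interval: float | str = NORMALIZED_2YR
    if sidecar_path.exists():
        interval = json.loads(sidecar_path.read_text())["interval_years"]
    return LogJacobianMap(
        values=np.asarray(img.dataobj, dtype=float),
        interval_years=interval,
        affine=np.asarray(img.affine),
    )
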