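"""Independent brute-force oracles used only by the tests.

Each oracle re-derives a quantity by the most literal method available
(triple loops, breadth-first search, 1-D likelihood maximization) and is
kept free of any code path it is used to check.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.optimize import minimize_scalar


def jacobian_determinant_loop(u: np.ndarray, voxel_size_mm) -> np.ndarray:
    """det(I + Du) built voxel-by-voxel with explicit finite differences:
    central in the interior, one-sided at grid boundaries."""
    nx, ny, nz, _ = u.shape
    h = voxel_size_mm
    out = np.empty((nx, ny, nz))

    def d(comp, axis, i, j, k):
        idx = [i, j, k]
        n_ax = u.shape[axis]
        if 0 < idx[axis] < n_ax - 1:
            lo, hi = list(idx), list(idx)
            lo[axis] -= 1
            hi[axis] += 1
            return (u[hi[0], hi[1], hi[2], comp] - u[lo[0], lo[1], lo[2], comp]) / (
                2 * h[axis]
            )
        if idx[axis] == 0:
            hi = list(idx)
            hi[axis] += 1
            return (u[hi[0], hi[1], hi[2], comp] - u[i, j, k, comp]) / h[axis]
        lo = list(idx)
        lo[axis] -= 1
        return (u[i, j, k, comp] - u[lo[0], lo[1], lo[2], comp]) / h[axis]

    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                J = np.eye(3)
                for c in range(3):
                    for a in range(3):
                        J[c, a] += d(c, a, i, j, k)
                out[i, j, k] = np.linalg.det(J)
    return out


def _neighbor_offsets(connectivity: int):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def bfs_label(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, list[int]]:
    """Connected-component labels and sizes by breadth-first search."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    offsets = _neighbor_offsets(connectivity)
    sizes = []
    next_label = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        next_label += 1
        labels[start] = next_label
        queue = deque([start])
        size = 0
        while queue:
            x, y, z = queue.popleft()
            size += 1
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= p[a] < mask.shape[a] for a in range(3)):
                    if mask[p] and not labels[p]:
                        labels[p] = next_label
                        queue.append(p)
        sizes.append(size)
    return labels, sizes


def efron_partial_loglik(beta: float, x, time, event) -> float:
    """Efron-approximation Cox partial log-likelihood, single covariate."""
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    eta = beta * x
    theta = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        d_set = (time == t) & (event == 1)
        risk = time >= t
        d = int(d_set.sum())
        sum_risk = theta[risk].sum()
        sum_tied = theta[d_set].sum()
        ll += eta[d_set].sum()
        for ell in range(d):
            ll -= np.log(sum_risk - (ell / d) * sum_tied)
    return float(ll)


def efron_mle(x, time, event, bound: float = 20.0) -> tuple[float, float]:
    """(beta_hat, max log-likelihood) by 1-D numerical maximization."""
    res = minimize_scalar(
        lambda b: -efron_partial_loglik(b, x, time, event),
        bounds=(-bound, bound),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), float(-res.fun)


def smoothed_noise_sd_factor(fwhm_mm: float, voxel_size_mm, grid_shape) -> float:
    """SD shrinkage factor of white noise under the generator's Gaussian
    smoothing, from the squared norm of the impulse response."""
    from scipy.ndimage import gaussian_filter

    delta = np.zeros(grid_shape)
    delta[tuple(s // 2 for s in grid_shape)] = 1.0
    sigma = [fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v for v in voxel_size_mm]
    k = gaussian_filter(delta, sigma=sigma, mode="nearest")
    return float(np.sqrt((k**2).sum()))
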