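"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths of the implementation: distances
come from explicit all-pairs enumeration (not an EDT), the maximal sphere
from a direct scan of every foreground candidate with voxel-by-voxel ball
rasterization, and the partial correlation from double residualization
(not a precision matrix).  They are only practical on tiny inputs.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import cdist

from mtlmorph.thickness import BinaryMask


def brute_force_distance_map(mask: BinaryMask) -> np.ndarray:
    """All-pairs distance from each foreground voxel center to the nearest
    background center, with a one-voxel exterior shell of background."""
    spacing = np.asarray(mask.spacing)
    padded = np.pad(mask.values, 1, constant_values=False)
    bg_idx = np.argwhere(~padded) - 1  # back to unpadded index frame
    fg_idx = np.argwhere(mask.values)
    bg_pts = bg_idx * spacing
    fg_pts = fg_idx * spacing
    out = np.zeros(mask.shape)
    d = cdist(fg_pts, bg_pts).min(axis=1)
    out[tuple(fg_idx.T)] = d
    return out


def ball_contained(mask: BinaryMask, center: np.ndarray, radius: float) -> bool:
    """Rasterize the closed ball: every voxel center inside it must be
    foreground (grid-exterior centers count as background)."""
    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    lo = np.floor((center - origin - radius) / spacing).astype(int)
    hi = np.ceil((center - origin + radius) / spacing).astype(int)
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            for k in range(lo[2], hi[2] + 1):
                p = origin + np.array([i, j, k]) * spacing
                if np.linalg.norm(p - center) <= radius:
                    inside_grid = (
                        0 <= i < mask.shape[0]
                        and 0 <= j < mask.shape[1]
                        and 0 <= k < mask.shape[2]
                    )
                    if not inside_grid or not mask.values[i, j, k]:
                        return False
    return True


def brute_force_max_sphere(
    mask: BinaryMask, dot, search_radius_mm: float | None = 10.0
) -> tuple[float, bool]:
    """Exhaustive maximal-sphere search: every foreground voxel center is a
    candidate with radius (distance to nearest background center - h/2);
    the winner's ball is verified by rasterization.  Returns (radius, valid).
    """
    dist = brute_force_distance_map(mask)
    h = min(mask.spacing)
    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    dot = np.asarray(dot, dtype=float)
    best = -np.inf
    best_center = None
    for idx in np.argwhere(mask.values):
        center = origin + idx * spacing
        r = dist[tuple(idx)] - h / 2.0
        d_dot = float(np.linalg.norm(center - dot))
        if search_radius_mm is not None and d_dot > search_radius_mm:
            continue
        if d_dot <= r + 1e-9 and r > best:
            best = r
            best_center = center
    if best_center is None:
        return math.nan, False
    assert ball_contained(mask, best_center, best), "oracle winner fails containment"
    return float(best), True


def residualized_partial_spearman(x, y, covariates) -> tuple[float, float]:
    """Partial Spearman via the residualization route: rank every variable
    on the complete cases, regress the x- and y-ranks on the covariate
    ranks (with intercept), and Pearson-correlate the residuals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    keep = ~np.isnan(np.column_stack([x, y, cov])).any(axis=1)
    x, y, cov = x[keep], y[keep], cov[keep]
    n, k = len(x), cov.shape[1]
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rz = np.column_stack([np.ones(n)] + [sps.rankdata(cov[:, j]) for j in range(k)])
    ex = rx - rz @ np.linalg.lstsq(rz, rx, rcond=None)[0]
    ey = ry - rz @ np.linalg.lstsq(rz, ry, rcond=None)[0]
    r = float(np.corrcoef(ex, ey)[0, 1])
    dof = n - 2 - k
    t = r * math.sqrt(dof / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return r, p


def random_blob_mask(rng: np.random.Generator, max_size: int = 14) -> BinaryMask:
    """A random connected-ish binary mask for oracle-equivalence tests."""
    shape = tuple(rng.integers(5, max_size + 1, size=3))
    spacing = tuple(rng.choice([0.2, 0.25, 0.5, 1.0], size=3))
    base = rng.random(shape)
    # crude box-average smoothing keeps blobs without using ndimage
    padded = np.pad(base, 1, mode="edge")
    smooth = np.zeros(shape)
    for di in range(3):
        for dj in range(3):
            for dk in range(3):
                smooth += padded[di : di + shape[0], dj : dj + shape[1], dk : dk + shape[2]]
    smooth /= 27.0
    values = smooth > np.quantile(smooth, rng.uniform(0.3, 0.7))
    if not values.any():
        values[tuple(s // 2 for s in shape)] = True
    return BinaryMask(values=values, spacing=spacing)
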