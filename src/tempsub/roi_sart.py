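"""ROI-weighted simultaneous algebraic reconstruction (SART) on a small
2-D parallel-beam geometry.

The system matrix W holds exact voxel-intersection lengths (Siddon-style
ray traversal over a unit-voxel grid).  For each ray i three scalars are
kept: l_G, the geometric chord length through the grid (exit minus entry
point); l_V, the summed intersection lengths over the voxels of a region
of interest; and k_ROI = l_V / l_G, the fraction of the ray's path inside
that ROI.  With no ROI the full grid is used, where l_V equals l_G
exactly and k_ROI = 1.

The update, swept angle block by angle block with relaxation lambda, is

    v_j  +=  lambda * sum_i w_ij * (k_i p_i - (W v)_i / l_G_i)
                    / sum_i w_ij * k_i          (i over the block's rays)

so measured data p are ray *means* (line integral / l_G).  Because the
full-grid row sums of W equal l_G, the k_ROI = 1 case is algebraically
the classic SART block iteration; the k factors down-weight rays by the
fraction of their path the ROI explains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

log = logging.getLogger(__name__)

__all__ = ["RayGeometry", "SartState", "build_projector", "forward_project", "sart_iterate"]


@dataclass
class RayGeometry:
    """Parallel-beam geometry over an n x n unit-voxel grid.

    Rays are indexed angle-major: ray ``a * n_detectors + d`` is detector
    ``d`` at angle ``angles[a]``.  ``weights`` is the (rays x voxels)
    sparse intersection-length matrix over row-major voxels.
    """

    grid_size: int
    angles: np.ndarray  # radians
    n_detectors: int
    weights: sparse.csr_matrix
    p_start: np.ndarray  # (rays, 2) entry points (x, y)
    p_end: np.ndarray  # (rays, 2) exit points
    l_g: np.ndarray  # geometric chord length per ray
    l_v: np.ndarray  # summed voxel crossings inside the ROI
    k_roi: np.ndarray  # l_v / l_g (0 for rays missing the grid)

    @property
    def n_rays(self) -> int:
        return len(self.l_g)

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    def ray_entries(self, i: int) -> list[tuple[tuple[int, int], float]]:
        """[(voxel (row, col), length), ...] for ray i."""
        row = self.weights.getrow(i)
        n = self.grid_size
        return [((j // n, j % n), float(w)) for j, w in zip(row.indices, row.data)]


@dataclass
class SartState:
    """Mutable reconstruction state."""

    volume: np.ndarray  # flat, length grid_size**2
    iteration: int = 0
    relax: float = 1.0
    residual_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.relax <= 2.0:
            raise ValueError(f"relaxation must lie in (0, 2], got {self.relax}")

    def image(self, grid_size: int) -> np.ndarray:
        return self.volume.reshape(grid_size, grid_size)


def _trace_ray(p0: np.ndarray, d: np.ndarray, n: int):
    """Siddon traversal of a ray p0 + t*d (|d| = 1) through [0, n]^2.

    Returns (voxel flat indices, segment lengths, t_entry, t_exit) or
    ``None`` when the ray misses the grid.
    """
    tmin, tmax = -np.inf, np.inf
    for axis in range(2):
        if abs(d[axis]) < 1e-12:
            if not (0.0 <= p0[axis] <= n):
                return None
        else:
            t0 = (0.0 - p0[axis]) / d[axis]
            t1 = (n - p0[axis]) / d[axis]
            tmin = max(tmin, min(t0, t1))
            tmax = min(tmax, max(t0, t1))
    if not np.isfinite(tmin) or not np.isfinite(tmax) or tmax - tmin <= 1e-12:
        return None

    crossings = [tmin, tmax]
    for axis in range(2):
        if abs(d[axis]) >= 1e-12:
            lo = p0[axis] + tmin * d[axis]
            hi = p0[axis] + tmax * d[axis]
            for k in range(int(np.ceil(min(lo, hi))), int(np.floor(max(lo, hi))) + 1):
                t = (k - p0[axis]) / d[axis]
                if tmin < t < tmax:
                    crossings.append(t)
    ts = np.unique(np.asarray(crossings))
    mids = (ts[:-1] + ts[1:]) / 2.0
    lengths = np.diff(ts)
    xm = p0[0] + mids * d[0]
    ym = p0[1] + mids * d[1]
    cols = np.clip(np.floor(xm).astype(int), 0, n - 1)
    rows = np.clip(np.floor(ym).astype(int), 0, n - 1)
    keep = lengths > 1e-12
    return rows[keep] * n + cols[keep], lengths[keep], float(tmin), float(tmax)


def build_projector(
    grid_size: int,
    angles,
    n_detectors: int,
    roi_mask: np.ndarray | None = None,
) -> RayGeometry:
    """Exact-intersection parallel-beam projector.

    Voxels are unit squares covering [0, n]^2 with row 0 at the top; the
    beam rotates about the grid centre with detector spacing equal to the
    voxel size.  At angle phi the ray direction is (cos phi, sin phi) and
    detectors are offset along (-sin phi, cos phi).  ``roi_mask`` (n x n
    boolean) restricts l_V; absent, the ROI is the full grid and
    k_ROI = 1 for every ray that crosses it.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        raise ValueError("angles must be non-empty")
    n = grid_size
    roi_flat = (
        np.ones(n * n, dtype=bool) if roi_mask is None
        else np.asarray(roi_mask, dtype=bool).ravel()
    )
    centre = np.array([n / 2.0, n / 2.0])
    offsets = np.arange(n_detectors, dtype=float) - (n_detectors - 1) / 2.0

    rows_idx, cols_idx, vals = [], [], []
    n_rays = len(angles) * n_detectors
    p_start = np.zeros((n_rays, 2))
    p_end = np.zeros((n_rays, 2))
    l_g = np.zeros(n_rays)
    l_v = np.zeros(n_rays)

    i = 0
    for phi in angles:
        d = np.array([np.cos(phi), np.sin(phi)])
        normal = np.array([-np.sin(phi), np.cos(phi)])
        for off in offsets:
            p0 = centre + off * normal
            hit = _trace_ray(p0, d, n)
            if hit is not None:
                vox, lens, tmin, tmax = hit
                rows_idx.extend([i] * len(vox))
                cols_idx.extend(vox.tolist())
                vals.extend(lens.tolist())
                p_start[i] = p0 + tmin * d
                p_end[i] = p0 + tmax * d
                l_g[i] = tmax - tmin
                l_v[i] = float(lens[roi_flat[vox]].sum())
            else:
                log.debug("ray %d misses the grid; excluded from updates", i)
            i += 1

    W = sparse.csr_matrix(
        (vals, (rows_idx, cols_idx)), shape=(n_rays, n * n), dtype=float
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(l_g > 0, l_v / np.maximum(l_g, 1e-300), 0.0)
    return RayGeometry(
        grid_size=n, angles=angles, n_detectors=n_detectors, weights=W,
        p_start=p_start, p_end=p_end, l_g=l_g, l_v=l_v, k_roi=k,
    )


def forward_project(geom: RayGeometry, volume: np.ndarray) -> np.ndarray:
    """Ray-mean sinogram: (W v)_i / l_G_i (0 for rays missing the grid)."""
    v = np.asarray(volume, dtype=float).ravel()
    raw = geom.weights @ v
    out = np.zeros_like(raw)
    hit = geom.l_g > 0
    out[hit] = raw[hit] / geom.l_g[hit]
    return out


def sart_iterate(
    state: SartState,
    geom: RayGeometry,
    measured: np.ndarray,
    n_iter: int = 1,
    use_roi_weights: bool = True,
) -> SartState:
    """Run ``n_iter`` full sweeps of the angle-sequential update.

    ``measured`` are ray means on the same layout as
    :func:`forward_project` output.  ``use_roi_weights=False`` forces
    k = 1 (classic SART) regardless of the geometry's ROI.  Voxels with a
    zero weight column in a block are left unchanged.  After each sweep
    the l2 norm of ``forward_project(v) - measured`` is appended to the
    residual history.
    """
    measured = np.asarray(measured, dtype=float).ravel()
    if measured.size != geom.n_rays:
        raise ValueError(
            f"measured has {measured.size} values, geometry has {geom.n_rays} rays"
        )
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    v = state.volume.astype(float).ravel().copy()
    k_all = geom.k_roi if use_roi_weights else (geom.l_g > 0).astype(float)
    nd = geom.n_detectors

    for _ in range(n_iter):
        for a in range(geom.n_angles):
            sl = slice(a * nd, (a + 1) * nd)
            Wb = geom.weights[sl]
            lg = geom.l_g[sl]
            k = k_all[sl]
            hit = lg > 0
            resid = np.zeros(nd)
            raw = Wb @ v
            resid[hit] = k[hit] * measured[sl][hit] - raw[hit] / lg[hit]
            num = Wb.T @ resid
            den = Wb.T @ k
            upd = np.zeros_like(v)
            nz = den > 0
            upd[nz] = num[nz] / den[nz]
            v += state.relax * upd
        state.iteration += 1
        state.residual_history.append(
            float(np.linalg.norm(forward_project(geom, v) - measured))
        )
    state.volume = v
    return state
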