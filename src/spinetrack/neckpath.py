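"""3D spine-neck path extraction and neck-length measurement.

The neck is traced as a geodesic through the fluorescence volume: each
z-slice is grey-eroded (suppressing thin spurious bridges), the eroded
intensity becomes a speed map, and an eikonal arrival-time field is computed
from the spine-head center.  Gradient descent (4th-order Runge–Kutta) from
each of the N dendrite-perimeter points nearest the head center yields N
candidate geodesics; the winner minimizes the sum of three max-normalized
terms — physical length L, complexity C (L1 norm of the coordinate
increments), and smoothness S (total intensity variation along the path).
The selected path is finally trimmed to the portion outside both the head
and dendrite masks; its length is the reported neck length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import ParameterError, TracingError, SpineTrackError
from .fastmarching import solve_eikonal
from .imgio import VoxelGeometry, ZStack

SPEED_FLOOR_FRAC = 1e-3      # ε floor as a fraction of max speed
RK_STEP_VOX = 0.25           # Runge–Kutta step, voxel units
RESAMPLE_STEP_VOX = 0.5      # uniform arclength step before C and S


@dataclass
class SpeedMap:
    values: np.ndarray
    erosion_radius: int
    geometry: VoxelGeometry


@dataclass
class NeckPath:
    points: np.ndarray                   # (K, 3) subvoxel (row, col, slice)
    L: float                             # physical length, μm
    C: float                             # complexity, voxel units
    S: float                             # intensity variation, a.u.
    cost: float = np.nan
    trimmed: bool = False
    flags: list = field(default_factory=list)

    @property
    def length_um(self) -> float:
        return self.L


def build_speed_map(stack: ZStack, erosion_radius: int = 1) -> SpeedMap:
    """Per-slice grey erosion, then normalization to (ε, 1]."""
    data = stack.data.astype(float)
    if data.size == 0:
        raise ParameterError("empty stack")
    if erosion_radius > 0:
        from skimage.morphology import disk
        footprint = disk(erosion_radius)
        eroded = np.stack([ndimage.grey_erosion(data[:, :, z], footprint=footprint)
                           for z in range(data.shape[2])], axis=-1)
    else:
        eroded = data
    if eroded.max() <= 0:
        raise ParameterError(
            "erosion removed all signal; use a smaller erosion_radius")
    # normalize by the raw maximum: erosion must *lower* the speed of thin
    # structures, not rescale the survivors back to 1
    speed = eroded / data.max()
    eps = SPEED_FLOOR_FRAC
    return SpeedMap(values=np.maximum(speed, eps), erosion_radius=erosion_radius,
                    geometry=stack.geometry)


def distance_map_3d(speed: SpeedMap, source) -> np.ndarray:
    """Arrival times from ``source`` (voxel index) through the speed map."""
    geom = speed.geometry
    spacing = (geom.dy, geom.dx, geom.dz if geom.dz is not None else geom.dx)
    return solve_eikonal(speed.values, source, spacing=spacing)


def _interp(vol: np.ndarray, p: np.ndarray) -> float:
    return float(ndimage.map_coordinates(vol, p[:, None], order=1, mode="nearest")[0])


def trace_path(distmap: np.ndarray, start, step: float = RK_STEP_VOX,
               max_steps: int = 100000) -> np.ndarray:
    """RK4 gradient descent on the arrival-time field, start → source.

    Descends in index space (monotone in T regardless of voxel anisotropy)
    and terminates within one voxel of the source (the field minimum).
    Raises :class:`TracingError` on stagnation.
    """
    start = np.asarray(start, dtype=float)
    t_start = _interp(distmap, start)
    if not np.isfinite(t_start):
        raise TracingError("start voxel has no finite arrival time")
    # cap the field at the start's arrival time for gradient purposes: voxels
    # that arrive later than the start are never on the geodesic, and their
    # (possibly enormous) values would otherwise dominate the interpolated
    # gradient near slow/fast interfaces
    capped = np.minimum(np.where(np.isfinite(distmap), distmap,
                                 t_start * 2.0), t_start * (1.0 + 1e-9))
    grads = np.gradient(capped)
    src = np.unravel_index(np.argmin(distmap), distmap.shape)
    src = np.asarray(src, dtype=float)
    shape = np.asarray(distmap.shape, dtype=float)

    def direction(p):
        g = np.array([_interp(gi, p) for gi in grads])
        n = np.linalg.norm(g)
        if n < 1e-12:
            return None
        return -g / n

    def discrete_descent(p, t_now):
        """Fallback: move toward the lowest-T point among unit offsets."""
        best, best_t = None, t_now - 1e-12
        for off in np.ndindex(3, 3, 3):
            off = np.asarray(off, dtype=float) - 1
            if not off.any():
                continue
            q = np.clip(p + off, 0, shape - 1)
            tq = _interp(distmap, q)
            if tq < best_t:
                best, best_t = q, tq
        return best

    path = [start.copy()]
    p = start.copy()
    t_prev = t_start
    stall = 0
    for _ in range(max_steps):
        if np.linalg.norm(p - src) <= 1.0:
            path.append(src.copy())
            break
        k1 = direction(p)
        if k1 is None:
            nxt = discrete_descent(p, t_prev)
            if nxt is None:
                raise TracingError("vanishing gradient before reaching the source")
            p = nxt
            t_prev = _interp(distmap, p)
            path.append(p.copy())
            continue
        k2 = direction(np.clip(p + 0.5 * step * k1, 0, shape - 1))
        k3 = direction(np.clip(p + 0.5 * step * (k2 if k2 is not None else k1), 0, shape - 1))
        k4 = direction(np.clip(p + step * (k3 if k3 is not None else k1), 0, shape - 1))
        ks = [k for k in (k1, k2, k3, k4) if k is not None]
        d = (k1 + 2 * (k2 if k2 is not None else k1) + 2 * (k3 if k3 is not None else k1)
             + (k4 if k4 is not None else k1)) / 6.0 if len(ks) == 4 else k1
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise TracingError("vanishing step")
        p = np.clip(p + step * d / n, 0, shape - 1)
        t_now = _interp(distmap, p)
        if t_now >= t_prev - 1e-12:
            stall += 1
            if stall > 8:
                nxt = discrete_descent(p, t_now)
                if nxt is None:
                    raise TracingError("descent stagnated before the source")
                p, t_now = nxt, _interp(distmap, nxt)
                stall = 0
        else:
            stall = 0
        t_prev = t_now
        path.append(p.copy())
    else:
        raise TracingError("maximum step count exceeded")
    return np.asarray(path)


def candidate_base_points(head_center, dendrite_mask: np.ndarray, N: int = 8,
                          geometry: Optional[VoxelGeometry] = None) -> np.ndarray:
    """The N dendrite-perimeter voxels nearest the head center (physical metric).

    A 2D dendrite mask is interpreted as lying in the head center's slice.
    Ties break by (row, col, slice).  If the perimeter holds fewer than N
    voxels, all are returned.
    """
    if N < 1:
        raise ParameterError("N must be >= 1")
    mask = np.asarray(dendrite_mask, dtype=bool)
    if not mask.any():
        raise ParameterError("empty dendrite mask")
    hc = np.asarray(head_center, dtype=float)
    if mask.ndim == 2:
        perim = mask & ~ndimage.binary_erosion(mask)
        pr, pc = np.nonzero(perim)
        pz = np.full_like(pr, int(round(hc[2])) if hc.size == 3 else 0)
        pts = np.column_stack([pr, pc, pz])
    elif mask.ndim == 3:
        perim = mask & ~ndimage.binary_erosion(mask)
        pts = np.column_stack(np.nonzero(perim))
    else:
        raise ParameterError("dendrite mask must be 2D or 3D")
    scale = np.array([geometry.dy, geometry.dx,
                      geometry.dz if geometry.dz is not None else geometry.dx]) \
        if geometry is not None else np.ones(3)
    d = np.linalg.norm((pts - hc[:3]) * scale, axis=1)
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], d))
    return pts[order[:min(N, len(pts))]]


def _resample(path: np.ndarray, step: float = RESAMPLE_STEP_VOX) -> np.ndarray:
    """Resample to uniform arclength steps (index space) so C and S are
    step-size independent."""
    if len(path) < 2:
        return path
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return path[:1]
    n = max(int(np.ceil(total / step)), 1)
    targets = np.linspace(0.0, total, n + 1)
    return np.column_stack([np.interp(targets, s, path[:, k]) for k in range(3)])


def path_terms(path: np.ndarray, stack: ZStack, geometry: VoxelGeometry,
               resample_step: float = RESAMPLE_STEP_VOX):
    """(L, C, S) of a voxel-space path.

    L: Σ physical segment lengths (μm, anisotropic); C: Σ |Δrow|+|Δcol|+|Δz|
    in voxel units; S: Σ |I(p_{k+1}) − I(p_k)| with trilinear sampling.
    C and S are computed on a uniform-arclength resampling of the path.
    """
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        raise ParameterError("path needs at least 2 points")
    shape = np.asarray(stack.data.shape)
    if path.min() < -0.5 or np.any(path > shape - 0.5):
        raise ParameterError("path point outside volume")
    scale = np.array([geometry.dy, geometry.dx,
                      geometry.dz if geometry.dz is not None else geometry.dx])
    diffs = np.diff(path, axis=0)
    L = float(np.linalg.norm(diffs * scale, axis=1).sum())
    rs = _resample(path, resample_step)
    rdiffs = np.diff(rs, axis=0)
    C = float(np.abs(rdiffs).sum())
    vol = stack.data.astype(float)
    intensities = ndimage.map_coordinates(vol, rs.T, order=1, mode="nearest")
    S = float(np.abs(np.diff(intensities)).sum())
    return L, C, S


def select_neck_path(candidates) -> NeckPath:
    """Pick the candidate minimizing the max-normalized L + C + S sum.

    ``candidates``: sequence of ``(path, L, C, S)``.  Terms whose maximum is
    zero are degenerate (identical across candidates) and contribute nothing;
    with a single candidate the cost equals the number of non-degenerate
    terms.  Ties break by input order.
    """
    cands = list(candidates)
    if not cands:
        raise SpineTrackError("no valid neck-path candidates")
    arr = np.array([[c[1], c[2], c[3]] for c in cands], dtype=float)
    maxima = arr.max(axis=0)
    costs = np.zeros(len(cands))
    for j in range(3):
        if maxima[j] > 0:
            costs += arr[:, j] / maxima[j]
    best = int(np.argmin(costs))
    path, L, C, S = cands[best]
    return NeckPath(points=np.asarray(path, dtype=float), L=L, C=C, S=S,
                    cost=float(costs[best]))


def _inside(mask: np.ndarray, p: np.ndarray) -> bool:
    if mask.ndim == 2:
        r, c = int(round(p[0])), int(round(p[1]))
        if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]:
            return bool(mask[r, c])
        return False
    r, c, z = (int(round(v)) for v in p)
    if all(0 <= v < s for v, s in zip((r, c, z), mask.shape)):
        return bool(mask[r, c, z])
    return False


def trim_path(path: NeckPath, head_mask: np.ndarray, dendrite_mask: np.ndarray,
              stack: ZStack, geometry: VoxelGeometry) -> NeckPath:
    """Remove the path portions inside the head and dendrite masks.

    Keeps the longest contiguous sub-path outside both masks and recomputes
    L, C, S on it.  A path that never touches both masks is returned
    unmodified (flagged); a fully-absorbed path (stubby spine with the head
    against the shaft) reports length 0 with a ``zero-length`` flag.
    """
    head = np.asarray(getattr(head_mask, "mask", head_mask), dtype=bool)
    dend = np.asarray(getattr(dendrite_mask, "mask", dendrite_mask), dtype=bool)
    pts = path.points
    in_head = np.array([_inside(head, p) for p in pts])
    in_dend = np.array([_inside(dend, p) for p in pts])
    if not (in_head.any() and in_dend.any()):
        return NeckPath(points=pts, L=path.L, C=path.C, S=path.S, cost=path.cost,
                        trimmed=True, flags=path.flags + ["untrimmed-endpoints"])
    outside = ~(in_head | in_dend)
    if not outside.any():
        return NeckPath(points=pts[:0], L=0.0, C=0.0, S=0.0, cost=path.cost,
                        trimmed=True, flags=path.flags + ["zero-length"])
    # longest contiguous outside run
    best_len, best_start = 0, 0
    run_len, run_start = 0, 0
    for i, o in enumerate(outside):
        if o:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len = 0
    sub = pts[best_start:best_start + best_len]
    if len(sub) < 2:
        return NeckPath(points=sub, L=0.0, C=0.0, S=0.0, cost=path.cost,
                        trimmed=True, flags=path.flags + ["zero-length"])
    L, C, S = path_terms(sub, stack, geometry)
    return NeckPath(points=sub, L=L, C=C, S=S, cost=path.cost, trimmed=True,
                    flags=list(path.flags))


def extract_neck(stack: ZStack, head_center, head_mask, dendrite_mask,
                 N: int = 8, erosion_radius: int = 1) -> NeckPath:
    """End-to-end neck extraction for one spine at one time point."""
    geometry = stack.geometry
    speed = build_speed_map(stack, erosion_radius=erosion_radius)
    T = distance_map_3d(speed, head_center)
    bases = candidate_base_points(head_center, np.asarray(
        getattr(dendrite_mask, "mask", dendrite_mask), dtype=bool), N, geometry)
    candidates = []
    for b in bases:
        try:
            p = trace_path(T, b.astype(float))
        except TracingError:
            continue
        try:
            L, C, S = path_terms(p, stack, geometry)
        except ParameterError:
            continue
        candidates.append((p, L, C, S))
    if not candidates:
        raise SpineTrackError("all candidate traces failed for this spine")
    best = select_neck_path(candidates)
    return trim_path(best, head_mask, dendrite_mask, stack, geometry)
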