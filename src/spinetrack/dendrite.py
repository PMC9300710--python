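"""Dendritic-shaft segmentation, medial axis, and the IFI normalizer.

The shaft (spines excluded) is recovered from a median-filtered MIP by Otsu
binarization, keeping the largest connected component, skeletonizing it, and
pruning the skeleton to the longest geodesic path (the medial axis).  At each
axis point a disk of locally adaptive radius — the Euclidean
distance-transform value clamped to the median radius ± a tolerance — is
kept; the union of disks is the shaft mask.  Protrusions beyond the clamped
radius (the spines) are thereby removed, under the assumption that the
dendrite's diameter is locally near-constant.  The median intensity inside
the shaft mask is the normalizer for IFI volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .errors import AmbiguityError, DegenerateInputError, SegmentationError
from .errors import ContractViolation, ParameterError
from .imgio import Image2D, median_filter2d


@dataclass
class DendriteMask:
    mask: np.ndarray            # boolean shaft mask
    medial_axis: np.ndarray     # (K, 2) ordered (row, col) path
    local_radius: np.ndarray    # (K,) clamped disk radius at each axis point
    median_intensity: float
    otsu_threshold: float


def otsu_threshold(image) -> float:
    """Threshold maximizing between-class variance over a 256-bin histogram.

    When several thresholds tie (e.g. an empty gap between two well-separated
    modes, where the between-class variance is flat), the mean of all
    maximizing bin centers is returned, placing the threshold mid-gap.
    """
    data = np.asarray(image.data if isinstance(image, Image2D) else image,
                      dtype=float).ravel()
    if np.ptp(data) == 0:
        raise DegenerateInputError("constant image has no Otsu threshold")
    hist, edges = np.histogram(data, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2.0
    p = hist / hist.sum()
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    mu = np.cumsum(p * centers)
    mu_total = mu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = mu[:-1] / w0
        m1 = (mu_total - mu[:-1]) / w1
        var = w0 * w1 * (m0 - m1) ** 2
    var[~np.isfinite(var)] = -np.inf
    best = var.max()
    ties = np.flatnonzero(var >= best * (1 - 1e-12))
    return float(centers[ties].mean())


def _longest_skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Ordered (row, col) path between the two farthest skeleton points.

    Double-BFS on the 8-connected skeleton graph: a BFS from an arbitrary
    skeleton pixel finds one extremity; a second BFS from there finds the
    farthest pixel and the path between them (the skeleton's diameter).
    """
    pts = np.column_stack(np.nonzero(skel))
    if len(pts) == 0:
        raise SegmentationError("empty skeleton")
    index = {tuple(p): i for i, p in enumerate(pts)}
    nbrs = [[] for _ in pts]
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for i, (r, c) in enumerate(pts):
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                nbrs[i].append(j)

    def bfs(start):
        dist = np.full(len(pts), -1, dtype=int)
        parent = np.full(len(pts), -1, dtype=int)
        dist[start] = 0
        queue = [start]
        far = start
        while queue:
            nxt = []
            for u in queue:
                for v in nbrs[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        parent[v] = u
                        nxt.append(v)
                        if dist[v] > dist[far]:
                            far = v
            queue = nxt
        return far, parent

    e1, _ = bfs(0)
    e2, parent = bfs(e1)
    path = []
    u = e2
    while u != -1:
        path.append(pts[u])
        u = parent[u]
    return np.asarray(path[::-1])


def segment_dendrite(mip: Image2D, median_window: int = 3,
                     radius_tolerance: float = 0.25,
                     select: str = "center") -> DendriteMask:
    """Segment the dendritic shaft (spines removed) from a MIP.

    ``radius_tolerance`` is the fractional clamp applied to the per-axis-point
    distance-transform radius (median ± tolerance), implementing the locally
    adaptive structuring element and the constant-diameter refinement in one
    rule.  When several equally large foreground components exist,
    ``select='center'`` analyzes the one containing (or nearest) the image
    center; ``select=<int>`` picks by size-rank index.
    """
    filtered = median_filter2d(mip, median_window)
    thr = otsu_threshold(filtered)
    fg = filtered.data > thr
    if not fg.any():
        raise SegmentationError("no foreground after Otsu thresholding")
    labels, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if n > 1 and sizes[order[0]] == sizes[order[1]] and not isinstance(select, int):
        if select == "center":
            center = (np.array(fg.shape) - 1) / 2.0
            best, best_d = None, np.inf
            for lab in (order[0] + 1, order[1] + 1):
                pts = np.column_stack(np.nonzero(labels == lab))
                d = np.linalg.norm(pts - center, axis=1).min()
                if d < best_d:
                    best, best_d = lab, d
            chosen = best
        else:
            raise AmbiguityError("multiple equally-large components",
                                 candidates=[int(order[0] + 1), int(order[1] + 1)])
    else:
        rank = select if isinstance(select, int) else 0
        chosen = int(order[rank] + 1)
    comp = labels == chosen

    skel = morphology.skeletonize(comp)
    axis = _longest_skeleton_path(skel)
    edt = ndimage.distance_transform_edt(comp)
    raw_radius = edt[axis[:, 0], axis[:, 1]]
    med_r = np.median(raw_radius)
    lo, hi = med_r * (1 - radius_tolerance), med_r * (1 + radius_tolerance)
    radius = np.clip(raw_radius, lo, hi)

    shaft = np.zeros_like(comp)
    rr_all, cc_all = np.mgrid[0:comp.shape[0], 0:comp.shape[1]]
    # union of disks: for efficiency, distance from every pixel to the axis
    # with per-axis-point radius via a max over chunks would be costly;
    # stamp disks directly instead
    for (r, c), rad in zip(axis, radius):
        ir = int(np.ceil(rad))
        r0, r1 = max(r - ir, 0), min(r + ir + 1, comp.shape[0])
        c0, c1 = max(c - ir, 0), min(c + ir + 1, comp.shape[1])
        sub = (rr_all[r0:r1, c0:c1] - r) ** 2 + (cc_all[r0:r1, c0:c1] - c) ** 2
        shaft[r0:r1, c0:c1] |= sub <= rad * rad
    shaft &= comp

    median_intensity = float(np.median(mip.data[shaft]))
    return DendriteMask(mask=shaft, medial_axis=axis, local_radius=radius,
                        median_intensity=median_intensity, otsu_threshold=thr)


def adjust_boundary(mask: np.ndarray, iterations: int, image=None,
                    level: float = None) -> np.ndarray:
    """Grow (positive iterations) or shrink (negative) a mask by curve evolution.

    Each iteration dilates or erodes by one pixel and applies a majority-vote
    curvature smoothing, so the boundary stays regular.  When ``level`` is
    given, growth never enters pixels whose intensity is below it (the
    intensity guidance); by default the evolution is purely geometric, which
    keeps growth strictly monotone on arbitrary images.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ParameterError("mask is empty")
    if iterations == 0:
        return m.copy()
    img = None
    if image is not None:
        img = np.asarray(image.data if isinstance(image, Image2D) else image, dtype=float)
    selem = morphology.disk(1)
    kernel = np.ones((3, 3))
    grow = iterations > 0
    for _ in range(abs(iterations)):
        if grow:
            new = morphology.dilation(m, selem)
            if level is not None and img is not None:
                new &= (img >= level) | m
            # curvature smoothing on the added ring only (never remove old pixels)
            counts = ndimage.convolve(new.astype(float), kernel, mode="constant")
            smoothed = new & (counts >= 5)
            m = m | smoothed
        else:
            new = morphology.erosion(m, selem)
            counts = ndimage.convolve(new.astype(float), kernel, mode="constant")
            m = new | (m & (counts >= 5) & new)
            m = new
        if not m.any():
            raise ContractViolation("mask shrank to empty")
    labels, n = ndimage.label(m)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        m = labels == (int(np.argmax(sizes)) + 1)
    return m
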