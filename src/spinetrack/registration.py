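"""Drift correction: global subpixel DFT registration + local NMI re-centering.

Global registration estimates a translational (dy, dx) between consecutive
time points by upsampled phase cross-correlation of the two maximum-intensity
projections, then applies the shift in the Fourier domain; an integer slice
offset dz is chosen afterwards by maximizing slice-wise correlation.

Local registration re-centers a spine's ROI at each time point by exhaustively
searching integer offsets within a Chebyshev radius and keeping the crop with
the highest normalized mutual information against the previous time point's
ROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .errors import DegenerateInputError, ParameterError
from .imgio import Image2D, TimeSeries, ZStack, max_intensity_projection

#: border width (px) contaminated by Fourier wrap-around after shifting;
#: downstream histogram statistics (Otsu) should ignore it
APODIZATION_BORDER_PX = 5


@dataclass(frozen=True)
class ShiftEstimate:
    """Displacement of the moving stack relative to the reference.

    ``mov ≈ ref translated by (dy, dx)`` in pixels; translating ``mov`` by
    ``(-dy, -dx)`` aligns it to ``ref``.  ``dz`` is an integer slice offset
    (None when not estimated).  ``peak_error`` is the phase-correlation
    residual reported by the estimator (lower is better).
    """

    dy: float
    dx: float
    dz: Optional[int] = None
    peak_error: float = 0.0


@dataclass(frozen=True)
class ROIWindow:
    """A square analysis window: center (row, col), half side, time point."""

    center: tuple
    half_size: int
    timepoint: int = 0

    def __post_init__(self):
        if self.half_size <= 0:
            raise ParameterError("half_size must be positive")

    def slices(self):
        r, c = self.center
        return (slice(r - self.half_size, r + self.half_size + 1),
                slice(c - self.half_size, c + self.half_size + 1))

    def crop(self, image: np.ndarray) -> np.ndarray:
        rs, cs = self.slices()
        if rs.start < 0 or cs.start < 0 or rs.stop > image.shape[0] or cs.stop > image.shape[1]:
            raise ParameterError("ROI window exceeds image bounds")
        return image[rs, cs]


def _fourier_translate2d(plane: np.ndarray, dy: float, dx: float) -> np.ndarray:
    out = np.fft.ifftn(ndimage.fourier_shift(np.fft.fftn(plane), (dy, dx)))
    return out.real


def translate_stack(stack: ZStack, dy: float, dx: float, dz: int = 0) -> ZStack:
    """Translate laterally by (dy, dx) (subpixel, Fourier) and axially by dz slices."""
    data = np.empty_like(stack.data, dtype=float)
    for z in range(stack.data.shape[2]):
        data[:, :, z] = _fourier_translate2d(stack.data[:, :, z].astype(float), dy, dx)
    if dz:
        data = np.roll(data, dz, axis=2)
        if dz > 0:
            data[:, :, :dz] = 0.0
        else:
            data[:, :, dz:] = 0.0
    return ZStack(np.clip(data, 0, None), stack.geometry)


def _best_dz(ref: np.ndarray, mov: np.ndarray) -> int:
    """Integer slice offset maximizing mean slice-wise correlation."""
    nz = ref.shape[2]
    if nz == 1:
        return 0
    best, best_dz = -np.inf, 0
    for dz in range(-(nz - 1), nz):
        if dz >= 0:
            a, b = ref[:, :, dz:], mov[:, :, :nz - dz]
        else:
            a, b = ref[:, :, :nz + dz], mov[:, :, -dz:]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        score = (a * b).sum() / denom if denom > 0 else -np.inf
        # prefer the smaller |dz| on ties so self-registration is the identity
        if score > best + 1e-12 or (abs(score - best) <= 1e-12 and abs(dz) < abs(best_dz)):
            best, best_dz = score, dz
    return best_dz


def global_register(ref: ZStack, mov: ZStack, upsample: int = 100,
                    estimate_dz: bool = True):
    """Estimate and correct the translational offset between two stacks.

    Returns ``(ShiftEstimate, registered ZStack)`` where the registered stack
    is ``mov`` translated by ``(-dy, -dx)`` (and ``-dz`` slices when
    estimated).
    """
    if ref.data.shape[:2] != mov.data.shape[:2]:
        raise ParameterError("stacks must share lateral shape")
    if upsample < 1:
        raise ParameterError("upsample must be >= 1")
    ref_mip = max_intensity_projection(ref).data.astype(float)
    mov_mip = max_intensity_projection(mov).data.astype(float)
    if np.ptp(ref_mip) == 0 or np.ptp(mov_mip) == 0:
        raise DegenerateInputError("constant image: no correlation peak")
    # phase_cross_correlation returns the shift that maps mov onto ref,
    # i.e. ref ≈ mov translated by `shift`; our dy/dx is the opposite sign.
    shift, error, _ = phase_cross_correlation(
        ref_mip, mov_mip, upsample_factor=upsample, normalization=None)
    dy, dx = -float(shift[0]), -float(shift[1])
    registered = translate_stack(mov, -dy, -dx)
    dz = None
    if estimate_dz and ref.data.shape[2] == mov.data.shape[2] and ref.data.shape[2] > 1:
        # _best_dz finds the offset aligning ref[..., dz:] with mov[..., :-dz];
        # in our convention (mov = ref shifted by +dz) the sign flips
        dz = -_best_dz(ref.data.astype(float), registered.data)
        if dz:
            registered = translate_stack(registered, 0.0, 0.0, -dz)
    return ShiftEstimate(dy=dy, dx=dx, dz=dz, peak_error=float(error)), registered


def register_timeseries(series: TimeSeries, upsample: int = 100,
                        estimate_dz: bool = True):
    """Chain-register each time point to its predecessor.

    Shifts are estimated between consecutive *raw* stacks, accumulated, and
    each stack is resampled exactly once with its accumulated shift (avoids
    repeated interpolation).  Returns ``(registered TimeSeries, [ShiftEstimate])``
    with one estimate per time point (the first is the identity).
    """
    shifts = [ShiftEstimate(0.0, 0.0, 0 if estimate_dz else None)]
    registered = [series.stacks[0]]
    acc_dy = acc_dx = 0.0
    acc_dz = 0
    prev_registered = series.stacks[0]
    for t in range(1, len(series)):
        # prev_registered is already aligned to t=0, so the estimate against
        # the raw stack t is the full accumulated drift of t
        est, _ = global_register(prev_registered, series.stacks[t],
                                 upsample=upsample, estimate_dz=estimate_dz)
        acc_dy = est.dy
        acc_dx = est.dx
        acc_dz = est.dz or 0
        shifts.append(ShiftEstimate(acc_dy, acc_dx,
                                    acc_dz if estimate_dz else None, est.peak_error))
        prev_registered = translate_stack(series.stacks[t], -acc_dy, -acc_dx,
                                          -acc_dz)
        registered.append(prev_registered)
    return TimeSeries(registered, list(series.timestamps)), shifts


def normalized_mutual_information(a, b, bins: int = 64) -> float:
    """NMI = (H(A) + H(B)) / H(A, B), in [1, 2]; 2 means perfect dependence.

    Each image is standardized to its own intensity range before joint
    histogramming with ``bins`` levels per axis.  A pair of constant images
    has zero entropies everywhere; the perfect-dependence limit 2 is returned.
    """
    a = np.asarray(a.data if isinstance(a, Image2D) else a, dtype=float).ravel()
    b = np.asarray(b.data if isinstance(b, Image2D) else b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ParameterError("images must share shape")
    if bins < 2:
        raise ParameterError("bins must be >= 2")

    def _standardize(x):
        rng = np.ptp(x)
        return (x - x.min()) / rng if rng > 0 else np.zeros_like(x)

    a_const, b_const = np.ptp(a) == 0, np.ptp(b) == 0
    if a_const and b_const:
        return 2.0
    joint, _, _ = np.histogram2d(_standardize(a), _standardize(b), bins=bins)
    pj = joint / joint.sum()
    pa = pj.sum(axis=1)
    pb = pj.sum(axis=0)

    def _entropy(p):
        p = p[p > 0]
        return -(p * np.log(p)).sum()

    h_joint = _entropy(pj.ravel())
    if h_joint == 0:
        return 2.0
    return float((_entropy(pa) + _entropy(pb)) / h_joint)


def local_register_roi(prev_roi_image, current_image, window: ROIWindow,
                       search_radius: int = 10, bins: int = 64) -> ROIWindow:
    """Re-center ``window`` in ``current_image`` by exhaustive NMI search.

    All integer offsets within Chebyshev distance ``search_radius`` whose crop
    stays inside the image are scored; the highest-NMI crop wins.  Ties go to
    the smallest offset magnitude, then row-major order, so radius 0 (or a
    flat NMI landscape) returns the input window.
    """
    if search_radius < 0:
        raise ParameterError("search_radius must be >= 0")
    prev = np.asarray(prev_roi_image.data if isinstance(prev_roi_image, Image2D)
                      else prev_roi_image, dtype=float)
    cur = np.asarray(current_image.data if isinstance(current_image, Image2D)
                     else current_image, dtype=float)
    h = window.half_size
    if 2 * h + 1 > min(cur.shape):
        raise ParameterError("ROI window larger than image")
    if search_radius == 0:
        return window

    offsets = []
    for dr in range(-search_radius, search_radius + 1):
        for dc in range(-search_radius, search_radius + 1):
            offsets.append((dr * dr + dc * dc, dr, dc))
    offsets.sort()  # magnitude, then row-major within equal magnitude

    r0, c0 = window.center
    best_nmi, best_center = -np.inf, window.center
    for _, dr, dc in offsets:
        r, c = r0 + dr, c0 + dc
        if r - h < 0 or c - h < 0 or r + h + 1 > cur.shape[0] or c + h + 1 > cur.shape[1]:
            continue
        crop = cur[r - h:r + h + 1, c - h:c + h + 1]
        score = normalized_mutual_information(prev, crop, bins=bins)
        if score > best_nmi + 1e-12:
            best_nmi, best_center = score, (r, c)
    return ROIWindow(best_center, h, window.timepoint)
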