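"""Raster I/O and the core image containers.

Conventions
-----------
* A z-stack is stored as an array of shape ``(M, N, Z)`` — rows, columns,
  slices.  TIFF pages hold one slice each, so files are transposed on
  read/write.
* All intensities are non-negative; 12-bit data lives in 16-bit containers
  and the configured bit depth wins over the container depth.
* Physical scale is carried by :class:`VoxelGeometry` (micrometres per pixel
  / per slice) and is the only place unit conversions happen.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
from scipy import ndimage

from .errors import LoadError, ParameterError, ShapeError

_ALLOWED_DEPTHS = (8, 12, 16)


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical sampling of the data: μm/pixel laterally, μm/slice axially."""

    dx: float
    dy: float
    dz: Optional[float] = None
    bit_depth: int = 16

    def __post_init__(self):
        if self.dx <= 0 or self.dy <= 0:
            raise ParameterError("pixel sizes dx, dy must be positive")
        if self.dz is not None and self.dz <= 0:
            raise ParameterError("slice spacing dz must be positive")
        if self.bit_depth not in _ALLOWED_DEPTHS:
            raise ParameterError(
                f"bit_depth must be one of {_ALLOWED_DEPTHS}, got {self.bit_depth}")

    @property
    def intensity_max(self) -> int:
        return 2 ** self.bit_depth - 1


def _check_intensities(data: np.ndarray, geometry: VoxelGeometry) -> None:
    if data.size and data.min() < 0:
        raise ShapeError("intensities must be non-negative")


@dataclass
class ZStack:
    """One acquisition: an ``(M, N, Z)`` intensity volume plus its geometry."""

    data: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[:, :, None]
        if self.data.ndim != 3 or self.data.shape[2] < 1:
            raise ShapeError(f"a z-stack must be (M, N, Z), got {self.data.shape}")
        _check_intensities(self.data, self.geometry)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class Image2D:
    """A single 2D frame (e.g. a maximum-intensity projection)."""

    data: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ShapeError(f"Image2D must be 2D, got {self.data.shape}")
        _check_intensities(self.data, self.geometry)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class TimeSeries:
    """Ordered z-stacks over T time points sharing lateral shape and geometry."""

    stacks: list
    timestamps: Sequence[float] = field(default_factory=list)

    def __post_init__(self):
        if not self.stacks:
            raise ShapeError("a time series needs at least one stack")
        m, n = self.stacks[0].data.shape[:2]
        for i, s in enumerate(self.stacks):
            if s.data.shape[:2] != (m, n):
                raise ShapeError(
                    f"stack {i} has lateral shape {s.data.shape[:2]}, expected {(m, n)}")
        if not len(self.timestamps):
            self.timestamps = list(range(len(self.stacks)))
        elif len(self.timestamps) != len(self.stacks):
            raise ShapeError("timestamps length must match number of stacks")

    def __len__(self):
        return len(self.stacks)

    @property
    def geometry(self) -> VoxelGeometry:
        return self.stacks[0].geometry


def _tiff_files(path: Path) -> list:
    exts = {".tif", ".tiff"}
    manifest = path / "manifest.txt"
    if manifest.exists():
        names = [ln.strip() for ln in manifest.read_text().splitlines() if ln.strip()]
        return [path / n for n in names]
    return sorted(p for p in path.iterdir() if p.suffix.lower() in exts)


def load_timeseries(path_spec, geometry: VoxelGeometry) -> TimeSeries:
    """Load a time series from one multi-page TIFF per time point.

    ``path_spec`` is either a directory (files sorted lexicographically, or
    ordered by a ``manifest.txt`` listing one filename per line) or a single
    TIFF file (T = 1).
    """
    path = Path(path_spec)
    if path.is_dir():
        files = _tiff_files(path)
        if not files:
            raise LoadError(f"no TIFF files found in {path}")
    elif path.is_file():
        files = [path]
    else:
        raise LoadError(f"no such file or directory: {path}")

    stacks = []
    shape2d = None
    for f in files:
        try:
            pages = tifffile.imread(os.fspath(f))
        except (OSError, ValueError) as exc:
            raise LoadError(f"cannot read TIFF {f}: {exc}") from exc
        if pages.ndim == 2:
            pages = pages[None]
        if pages.ndim != 3:
            raise ShapeError(f"{f}: expected 2D/3D TIFF, got shape {pages.shape}")
        data = np.moveaxis(pages, 0, -1)  # (Z, M, N) -> (M, N, Z)
        if shape2d is None:
            shape2d = data.shape[:2]
        elif data.shape[:2] != shape2d:
            raise ShapeError(
                f"{f}: lateral shape {data.shape[:2]} differs from first stack {shape2d}")
        stacks.append(ZStack(data, geometry))
    return TimeSeries(stacks)


def save_stack(path, stack: ZStack) -> None:
    """Write a z-stack as a multi-page TIFF, one page per slice."""
    pages = np.moveaxis(stack.data, -1, 0)
    tifffile.imwrite(os.fspath(path), pages, photometric="minisblack")


def save_image(path, image) -> None:
    data = image.data if hasattr(image, "data") else np.asarray(image)
    tifffile.imwrite(os.fspath(path), data, photometric="minisblack")


def max_intensity_projection(stack: ZStack) -> Image2D:
    """Per-pixel maximum across z: the 2D working image of the pipeline."""
    if stack.data.shape[2] < 1:
        raise ShapeError("empty stack")
    return Image2D(stack.data.max(axis=2), stack.geometry)


def median_filter2d(image: Image2D, window: int) -> Image2D:
    """Median-filter with a ``window``×``window`` kernel, edge-replicated borders."""
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"median window must be odd and >= 1, got {window}")
    if window == 1:
        return Image2D(image.data.copy(), image.geometry)
    out = ndimage.median_filter(image.data, size=window, mode="nearest")
    return Image2D(out, image.geometry)


def default_median_window(dx_um: float) -> int:
    """Guideline window: 3 px at ≥ 0.03 μm/px sampling, 5 px for finer sampling."""
    return 3 if dx_um >= 0.03 else 5
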