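"""Spine-head volume estimation and time-series agreement scores.

Two volume proxies are provided:

* **IFI** (integrated fluorescence intensity): the sum of intensities inside
  the segmented head, minus a background term (minimum intensity in the
  spine's field of view × mask area), normalized by the median intensity of
  the segmented dendritic shaft.  The normalization makes the readout
  invariant to global fluorescence changes (laser power, bleaching).
* **FWHM**: a Gaussian (+ constant offset) is fitted to an intensity profile
  along a line through the head center, oriented parallel to the postsynaptic
  density; the full width at half maximum is taken as the diameter of an
  equivalent sphere and volume = 4/3·π·r³ in μm³.

Agreement between two volume time series is scored with the symmetric mean
absolute percentage error sMAPE = 100·(1/t)·Σ|aᵢ−bᵢ|/|aᵢ+bᵢ| and the
similarity score SS = 100 − sMAPE (both in percent).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize

from .errors import FitError, NormalizationError, ParameterError
from .imgio import Image2D

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


@dataclass(frozen=True)
class IFIMeasurement:
    raw_sum: float
    background: float
    area_px: int
    dendrite_median: float
    normalized_volume: float
    clamped: bool = False


@dataclass(frozen=True)
class FWHMMeasurement:
    profile: np.ndarray
    spacing_um: float
    amplitude: float
    mean_um: float
    sigma_um: float
    offset: float
    fwhm_um: float
    radius_um: float
    volume_um3: float
    orientation_deg: float


@dataclass(frozen=True)
class TrendComparison:
    series_a: np.ndarray
    series_b: np.ndarray
    t: int
    smape: float
    ss: float


def ifi_volume(roi, mask, fov_min: float, dendrite_median: float) -> IFIMeasurement:
    """Background-subtracted, dendrite-normalized integrated intensity.

    ``mask`` may be a boolean array in ROI coordinates or any object with a
    boolean ``mask`` attribute.  A negative background-subtracted sum is
    clamped to zero and flagged rather than raised, so dim time points do not
    abort a longitudinal run.
    """
    data = np.asarray(roi.data if isinstance(roi, Image2D) else roi, dtype=float)
    m = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if m.shape != data.shape:
        raise ParameterError("mask and ROI shapes differ")
    area = int(m.sum())
    if area == 0:
        raise ParameterError("empty spine mask")
    if dendrite_median <= 0:
        raise NormalizationError("dendrite median intensity must be positive")
    raw = float(data[m].sum())
    background = float(fov_min) * area
    num = raw - background
    clamped = num < 0
    if clamped:
        num = 0.0
    return IFIMeasurement(raw_sum=raw, background=background, area_px=area,
                          dendrite_median=float(dendrite_median),
                          normalized_volume=num / dendrite_median,
                          clamped=clamped)


def _gaussian_offset(x, amp, mu, sigma, off):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2)) + off


def fit_gaussian_profile(profile: np.ndarray, spacing_um: float):
    """Least-squares Gaussian+offset fit; returns (amp, mu, sigma, offset) in μm units."""
    y = np.asarray(profile, dtype=float)
    if y.size < 5:
        raise FitError("profile too short for a Gaussian fit")
    x = np.arange(y.size) * spacing_um
    off0 = y.min()
    amp0 = y.max() - off0
    if amp0 <= 0:
        raise FitError("flat profile: no peak to fit")
    mu0 = x[int(np.argmax(y))]
    sigma0 = max(spacing_um, (x[-1] - x[0]) / 8.0)
    try:
        popt, _ = optimize.curve_fit(
            _gaussian_offset, x, y, p0=(amp0, mu0, sigma0, off0),
            bounds=([0, x[0], spacing_um * 0.1, -np.inf],
                    [np.inf, x[-1], (x[-1] - x[0]), np.inf]),
            maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    amp, mu, sigma, off = map(float, popt)
    if sigma > 0.5 * (x[-1] - x[0]):
        raise FitError("fitted width exceeds half the profile length")
    return amp, mu, sigma, off


def sample_line_profile(roi, center, orientation_deg: float,
                        line_length_um: float, spacing_um: Optional[float] = None):
    """Interpolate intensities along an oriented line through ``center``.

    ``orientation_deg`` is measured from the +column axis, counter-clockwise
    in image coordinates.  Returns ``(profile, spacing_um)``.
    """
    data = np.asarray(roi.data if isinstance(roi, Image2D) else roi, dtype=float)
    geom = roi.geometry if isinstance(roi, Image2D) else None
    dx = geom.dx if geom is not None else 1.0
    if spacing_um is None:
        spacing_um = dx / 2.0
    n = int(round(line_length_um / spacing_um)) + 1
    if n < 5:
        raise ParameterError("line too short for a usable profile")
    theta = np.deg2rad(orientation_deg)
    s = (np.arange(n) - (n - 1) / 2.0) * spacing_um
    rows = center[0] - s * np.sin(theta) / dx
    cols = center[1] + s * np.cos(theta) / dx
    if rows.min() < 0 or cols.min() < 0 or rows.max() > data.shape[0] - 1 \
            or cols.max() > data.shape[1] - 1:
        raise ParameterError("profile line exceeds the ROI")
    profile = ndimage.map_coordinates(data, np.vstack([rows, cols]), order=3)
    return profile, spacing_um


def fwhm_volume(roi, center, orientation_deg: float,
                line_length_um: float) -> FWHMMeasurement:
    """Sphere-model volume from the FWHM of a fitted line profile.

    The orientation is an explicit parameter: the PSD-parallel direction is
    chosen by the analyst, not searched automatically.
    """
    profile, spacing = sample_line_profile(roi, center, orientation_deg, line_length_um)
    amp, mu, sigma, off = fit_gaussian_profile(profile, spacing)
    fwhm = _FWHM_PER_SIGMA * sigma
    r = fwhm / 2.0
    return FWHMMeasurement(profile=profile, spacing_um=spacing, amplitude=amp,
                           mean_um=mu, sigma_um=sigma, offset=off, fwhm_um=fwhm,
                           radius_um=r, volume_um3=(4.0 / 3.0) * np.pi * r ** 3,
                           orientation_deg=orientation_deg)


def normalize_to_baseline(series: Sequence[float], baseline_idx) -> np.ndarray:
    """Divide a series by its mean over the baseline time points."""
    values = np.asarray(series, dtype=float)
    idx = np.asarray(list(baseline_idx), dtype=int)
    if idx.size == 0:
        raise ParameterError("baseline index set is empty")
    base = values[idx].mean()
    if base <= 0:
        raise NormalizationError("baseline mean must be positive")
    return values / base


def smape(series_a, series_b) -> float:
    """Symmetric MAPE in percent: 100·(1/t)·Σ|aᵢ−bᵢ|/|aᵢ+bᵢ| ∈ [0, 100]."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ParameterError("series must be equal-length 1D with t >= 1")
    num = np.abs(a - b)
    den = np.abs(a + b)
    terms = np.zeros_like(num)
    nonzero = den > 0
    terms[nonzero] = num[nonzero] / den[nonzero]
    if np.any(~nonzero & (num > 0)):
        raise ParameterError("a_i + b_i = 0 with a_i != b_i: sMAPE undefined")
    return float(100.0 * terms.mean())


def similarity_score(series_a, series_b) -> float:
    """SS = 100 − sMAPE (percent); 100 means identical trends."""
    return 100.0 - smape(series_a, series_b)


def compare_trends(series_a, series_b) -> TrendComparison:
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    s = smape(a, b)
    return TrendComparison(series_a=a, series_b=b, t=a.size, smape=s, ss=100.0 - s)


# ---------------------------------------------------------------------------
# result export

def export_results(records, out_dir, config: Optional[dict] = None,
                   seed: Optional[int] = None) -> dict:
    """Write per-spine time-series CSVs, mask TIFFs and a JSON run manifest.

    ``records`` is a sequence of :class:`spinetrack.pipeline.SpineRecord`.
    Missing (flagged) time points export as empty cells, never as zeros.
    Returns a dict of written paths.
    """
    import pandas as pd
    from .imgio import save_image

    if not records:
        raise ParameterError("no records to export")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {"csv": [], "masks": [], "manifest": None}

    for rec in records:
        rows = []
        for t, entry in enumerate(rec.timepoints):
            row = {"t": t, "spine_id": rec.spine_id}
            if entry.get("missing"):
                row.update({"area_px": "", "ifi_raw": "", "ifi_normalized": "",
                            "fwhm_volume_um3": "", "neck_length_um": ""})
            else:
                ifi = entry.get("ifi")
                fwhm = entry.get("fwhm")
                neck = entry.get("neck")
                mask = entry.get("mask")
                row["area_px"] = getattr(mask, "area_px", "") if mask is not None else ""
                row["ifi_raw"] = f"{ifi.raw_sum:.6g}" if ifi else ""
                row["ifi_normalized"] = f"{ifi.normalized_volume:.6g}" if ifi else ""
                row["fwhm_volume_um3"] = f"{fwhm.volume_um3:.6g}" if fwhm else ""
                row["neck_length_um"] = f"{neck.length_um:.6g}" if neck else ""
            row["flags"] = ";".join(entry.get("flags", []))
            rows.append(row)
        df = pd.DataFrame(rows)
        csv_path = out / f"spine_{rec.spine_id:03d}.csv"
        df.to_csv(csv_path, index=False)
        written["csv"].append(csv_path)

        masks = [e.get("mask") for e in rec.timepoints]
        if any(m is not None for m in masks):
            shape = next(m.mask.shape for m in masks if m is not None)
            labeled = np.zeros((len(masks),) + shape, dtype=np.uint16)
            for t, m in enumerate(masks):
                if m is not None and m.mask.shape == shape:
                    labeled[t] = m.mask.astype(np.uint16)
            mask_path = out / f"spine_{rec.spine_id:03d}_masks.tif"
            save_image(mask_path, labeled)
            written["masks"].append(mask_path)

    manifest = {
        "n_spines": len(records),
        "n_timepoints": len(records[0].timepoints),
        "seed": seed,
        "config": config or {},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    written["manifest"] = manifest_path
    return written
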