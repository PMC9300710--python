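"""End-to-end orchestration: load → register → detect → segment → measure → export.

Spine identity is defined by the detections at the first time point; later
time points inherit each spine's ROI through NMI local registration rather
than re-detection (a ``redetect`` mode adds newly appearing spines for
turnover studies).  Per-spine failures degrade to flags so a longitudinal
run always completes; reruns with the same config and seed reproduce
byte-identical measurement CSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import morphometry
from .errors import ParameterError, SpineTrackError
from .imgio import (Image2D, TimeSeries, VoxelGeometry, load_timeseries,
                    max_intensity_projection, median_filter2d)
from .registration import register_timeseries
from .spines import segment_spine_timeseries
from .dendrite import segment_dendrite


_CONFIG_FIELDS = {
    "input_path": None,
    "output_dir": "spinetrack_run",
    "pixel_size_um": 0.072,
    "z_step_um": None,
    "bit_depth": 12,
    "median_window": 3,
    "upsample": 100,
    "search_radius": 10,
    "roi_half_size": 24,
    "mock_radius_um": 0.6,
    "cluster_intensity_fraction": 0.5,
    "neck_candidates": 8,
    "erosion_radius": 1,
    "patch_um": 3.4,
    "nms_radius_um": 0.5,
    "confidence_threshold": 0.5,
    "fwhm_orientation_deg": None,
    "fwhm_line_length_um": 2.0,
    "redetect": False,
    "seed": 0,
    "log_level": "INFO",
}


@dataclass
class RunConfig:
    """Serializable run configuration; unknown keys are rejected."""

    values: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.values) - set(_CONFIG_FIELDS)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_CONFIG_FIELDS)
        merged.update(self.values)
        self.values = merged

    def __getattr__(self, name):
        values = object.__getattribute__(self, "values")
        if name in values:
            return values[name]
        raise AttributeError(name)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(values=data)

    def geometry(self) -> VoxelGeometry:
        return VoxelGeometry(dx=self.pixel_size_um, dy=self.pixel_size_um,
                             dz=self.z_step_um, bit_depth=self.bit_depth)

    def non_default(self) -> dict:
        return {k: v for k, v in self.values.items() if v != _CONFIG_FIELDS[k]}


@dataclass
class SpineRecord:
    """One spine tracked across all time points."""

    spine_id: int
    timepoints: list = field(default_factory=list)  # dict per time point


def analyze_series(series: TimeSeries, centers, config: RunConfig,
                   classifier=None):
    """Measure every spine given t=0 centers on an already-registered series.

    Returns a list of :class:`SpineRecord`.  Per-time-point entries carry the
    ROI window, head mask, IFI measurement, optional FWHM measurement, neck
    path (3D data only), and flags.
    """
    records = []
    mips = [median_filter2d(max_intensity_projection(s), config.median_window)
            for s in series.stacks]
    dendrites = []
    for mip in mips:
        try:
            dendrites.append(segment_dendrite(mip, config.median_window))
        except SpineTrackError:
            dendrites.append(None)

    for sid, center in enumerate(centers):
        masks, windows = segment_spine_timeseries(
            series, center, half_size=config.roi_half_size,
            search_radius=config.search_radius,
            mock_radius_um=config.mock_radius_um,
            f=config.cluster_intensity_fraction)
        rec = SpineRecord(spine_id=sid)
        for t, (mask, window) in enumerate(zip(masks, windows)):
            entry = {"window": window, "mask": None, "ifi": None, "fwhm": None,
                     "neck": None, "flags": [], "missing": False}
            if mask.missing or mask.area_px == 0:
                entry["missing"] = True
                entry["flags"].append("missing")
                rec.timepoints.append(entry)
                continue
            entry["mask"] = mask
            if mask.provenance == "mock-boundary":
                entry["flags"].append("mock")
            roi = window.crop(mips[t].data.astype(float))
            dend = dendrites[t]
            if dend is not None and dend.median_intensity > 0:
                try:
                    entry["ifi"] = morphometry.ifi_volume(
                        roi, mask.mask, float(roi.min()), dend.median_intensity)
                    if entry["ifi"].clamped:
                        entry["flags"].append("ifi-clamped")
                except SpineTrackError:
                    entry["flags"].append("ifi-failed")
            else:
                entry["flags"].append("no-dendrite")
            if config.fwhm_orientation_deg is not None:
                try:
                    roi_img = Image2D(roi, series.geometry)
                    entry["fwhm"] = morphometry.fwhm_volume(
                        roi_img, mask.seed, config.fwhm_orientation_deg,
                        config.fwhm_line_length_um)
                except SpineTrackError:
                    entry["flags"].append("fwhm-failed")
            if series.geometry.dz is not None and series.stacks[t].data.shape[2] > 1 \
                    and dend is not None:
                try:
                    from .neckpath import extract_neck
                    rs, cs = window.slices()
                    head_full = np.zeros(mips[t].data.shape, dtype=bool)
                    head_full[rs, cs] = mask.mask
                    gr = window.center[0] - config.roi_half_size + mask.seed[0]
                    gc = window.center[1] - config.roi_half_size + mask.seed[1]
                    z_mid = series.stacks[t].data.shape[2] // 2
                    neck = extract_neck(series.stacks[t], (gr, gc, z_mid),
                                        head_full, dend.mask,
                                        N=config.neck_candidates,
                                        erosion_radius=config.erosion_radius)
                    entry["neck"] = neck
                    if "zero-length" in neck.flags:
                        entry["flags"].append("zero-neck")
                except SpineTrackError:
                    entry["flags"].append("neck-failed")
            rec.timepoints.append(entry)
        records.append(rec)
    return records


def run_pipeline(config: RunConfig, series: Optional[TimeSeries] = None,
                 classifier=None, centers=None) -> Path:
    """Execute the full workflow and write results to the run directory.

    ``series`` may be supplied directly (e.g. from the simulator); otherwise
    it is loaded from ``config.input_path``.  ``centers`` (t=0 spine centers)
    may be supplied to skip detection, e.g. from a manual-centers CSV; a
    classifier is required otherwise.
    """
    if series is None:
        if not config.input_path:
            raise ParameterError("config.input_path is required")
        series = load_timeseries(config.input_path, config.geometry())

    registered, shifts = register_timeseries(series, upsample=config.upsample) \
        if len(series) > 1 else (series, [])

    if centers is None:
        if classifier is None:
            raise ParameterError("either centers or a trained classifier is required")
        from .detection import detect_spines
        mip0 = median_filter2d(max_intensity_projection(registered.stacks[0]),
                               config.median_window)
        detections = detect_spines(mip0, classifier,
                                   nms_radius_um=config.nms_radius_um,
                                   patch_um=config.patch_um,
                                   confidence_threshold=config.confidence_threshold)
        centers = [(r, c) for r, c, _ in detections]

    records = analyze_series(registered, centers, config, classifier=classifier)

    out = Path(config.output_dir)
    morphometry.export_results(records, out, config=config.non_default(),
                               seed=config.seed)
    if shifts:
        import pandas as pd
        pd.DataFrame([{"t": t, "dy": s.dy, "dx": s.dx, "dz": s.dz}
                      for t, s in enumerate(shifts)]).to_csv(
            out / "shifts.csv", index=False)
    return out


def merge_manual_inputs(run_dir, config: RunConfig, series: TimeSeries,
                        manual_centers: Optional[str] = None,
                        manual_masks: Optional[dict] = None):
    """Apply manual corrections and recompute only the affected spines.

    ``manual_centers``: CSV path with columns (row, col) of extra t=0
    centers; ``manual_masks``: mapping ``(spine_id, t) -> bool mask`` that
    overrides the automatic mask for that time point.  Returns the new
    records for the affected spines only (other spines' outputs on disk are
    untouched).
    """
    import pandas as pd

    added = []
    if manual_centers:
        try:
            df = pd.read_csv(manual_centers)
        except Exception as exc:
            raise ParameterError(f"malformed manual centers CSV: {exc}") from exc
        for i, row in df.iterrows():
            try:
                added.append((int(row["row"]), int(row["col"])))
            except (KeyError, ValueError) as exc:
                raise ParameterError(f"manual centers CSV row {i}: {exc}") from exc
    new_records = analyze_series(series, added, config) if added else []
    if manual_masks:
        for (sid, t), mask in manual_masks.items():
            for rec in new_records:
                if rec.spine_id == sid and t < len(rec.timepoints):
                    entry = rec.timepoints[t]
                    if entry["mask"] is not None:
                        entry["mask"].mask = np.asarray(mask, dtype=bool)
                        entry["flags"].append("manual-mask")
    return new_records
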