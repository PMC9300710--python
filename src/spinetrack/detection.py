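"""Spine detection: blob candidates + CNN patch classification.

Candidate locations are local maxima of a determinant-of-Hessian scale-space
response (the interest-point stage underlying SURF-style detectors; only the
locations are used, never descriptors).  A fixed physical-size patch
(default 3.4 μm square — 97 px at 0.035 μm/px sampling) is cropped around
each candidate and classified into nine dendritic-feature classes by
:class:`spinetrack.cnn.PatchClassifier`; candidates classified as spine heads
above a confidence threshold are merged by non-maximum suppression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.feature import hessian_matrix_det, peak_local_max

from .cnn import PatchClassifier
from .errors import ParameterError
from .imgio import Image2D, TimeSeries, max_intensity_projection, median_filter2d

SPINE_CLASS = 1

PATCH_CLASS_NAMES = {
    1: "spine head", 2: "multiple overlapping spines",
    3: "spine-dendrite junction", 4: "dendrite edge", 5: "dendrite",
    6: "spine neck", 7: "spine head edge", 8: "bouton/axon", 9: "noise",
}


@dataclass(frozen=True)
class InterestPoint:
    row: int
    col: int
    scale: float
    response: float


@dataclass
class LabeledPatch:
    pixels: np.ndarray
    center: tuple
    label: Optional[int] = None
    confidence: Optional[float] = None


@dataclass(frozen=True)
class ClassifierConfig:
    """Declarative description of the patch network."""

    n_classes: int = 9
    conv_blocks: int = 6
    block_spec: tuple = (16, 32, 48, 64, 96, 128)
    fc_sizes: tuple = (4096, 256)
    activation: str = "swish"
    pooling: str = "max"
    normalization: str = "batch"
    seed: int = 0

    def __post_init__(self):
        if self.n_classes not in (2, 9):
            raise ParameterError("n_classes must be 9 (in-vitro) or 2 (in-vivo)")
        if self.conv_blocks != 6 or len(self.block_spec) != 6:
            raise ParameterError("the network has exactly six convolutional blocks")


def detect_interest_points(mip, threshold: float = 0.0005,
                           sigmas: Sequence[float] = (2.0, 3.0, 4.0, 6.0),
                           min_distance: int = 3):
    """Scale-space determinant-of-Hessian maxima above ``threshold``.

    The image is range-normalized to [0, 1] first, so the threshold is
    intensity-scale free.  Returns points sorted by descending response;
    a constant image yields an empty list.
    """
    data = np.asarray(mip.data if isinstance(mip, Image2D) else mip, dtype=float)
    rng = np.ptp(data)
    if rng == 0:
        return []
    norm = (data - data.min()) / rng
    response = np.zeros_like(norm)
    best_sigma = np.zeros_like(norm)
    for s in sigmas:
        doh = hessian_matrix_det(norm, sigma=s)
        better = doh > response
        response[better] = doh[better]
        best_sigma[better] = s
    peaks = peak_local_max(response, min_distance=min_distance,
                           threshold_abs=threshold, exclude_border=False)
    points = [InterestPoint(int(r), int(c), float(best_sigma[r, c]),
                            float(response[r, c]))
              for r, c in peaks]
    points.sort(key=lambda p: (-p.response, p.row, p.col))
    return points


def extract_patch(image, center, patch_um: float = 3.4) -> LabeledPatch:
    """Crop a square patch of fixed physical size, zero-padded at borders.

    The pixel side is ``round(patch_um / dx)`` forced odd, so the patch is
    exactly centered on ``center``.
    """
    if patch_um <= 0:
        raise ParameterError("patch_um must be positive")
    data = np.asarray(image.data if isinstance(image, Image2D) else image, dtype=float)
    dx = image.geometry.dx if isinstance(image, Image2D) else 1.0
    side = int(round(patch_um / dx))
    if side % 2 == 0:
        side += 1
    half = side // 2
    r, c = int(center[0]), int(center[1])
    patch = np.zeros((side, side), dtype=float)
    r0, r1 = max(r - half, 0), min(r + half + 1, data.shape[0])
    c0, c1 = max(c - half, 0), min(c + half + 1, data.shape[1])
    patch[r0 - (r - half):r0 - (r - half) + (r1 - r0),
          c0 - (c - half):c0 - (c - half) + (c1 - c0)] = data[r0:r1, c0:c1]
    return LabeledPatch(pixels=patch, center=(r, c))


def collapse_to_two_classes(labels: np.ndarray) -> np.ndarray:
    """In-vivo mode: classes 2–9 collapse into a single non-spine class (2)."""
    labels = np.asarray(labels)
    return np.where(labels == SPINE_CLASS, SPINE_CLASS, 2)


def train_classifier(patches, labels, config: Optional[ClassifierConfig] = None,
                     split: float = 0.3, small: bool = False, **fit_overrides):
    """Train the patch network; returns (classifier, train_cm, val_cm).

    ``split`` is the validation fraction (the best-validation-accuracy
    checkpoint is kept).  ``small=True`` selects the desk-scale profile.
    """
    from sklearn.metrics import confusion_matrix

    X = np.asarray([p.pixels if isinstance(p, LabeledPatch) else p for p in patches],
                   dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ParameterError("training needs at least two classes")
    config = config or ClassifierConfig()
    if config.n_classes == 2:
        y = collapse_to_two_classes(y)
    kw = dict(val_fraction=split, seed=config.seed)
    kw.update(fit_overrides)
    clf = PatchClassifier.small(**kw) if small else PatchClassifier(
        conv_channels=config.block_spec, fc_sizes=config.fc_sizes, **kw)
    clf.fit(X, y)
    labels_all = clf.classes_
    pred_train = clf.predict(X[clf._train_idx])
    pred_val = clf.predict(X[clf._val_idx])
    cm_train = confusion_matrix(y[clf._train_idx], pred_train, labels=labels_all)
    cm_val = confusion_matrix(y[clf._val_idx], pred_val, labels=labels_all)
    return clf, cm_train, cm_val


def _nms(rows, cols, confidences, radius_px: float):
    order = np.lexsort((cols, rows, -np.asarray(confidences)))
    kept = []
    for i in order:
        p = np.array([rows[i], cols[i]], dtype=float)
        if all(np.linalg.norm(p - np.array([rows[j], cols[j]])) >= radius_px
               for j in kept):
            kept.append(i)
    return sorted(kept, key=lambda j: (rows[j], cols[j]))


def detect_spines(mip: Image2D, classifier: PatchClassifier,
                  nms_radius_um: float = 0.5, patch_um: float = 3.4,
                  confidence_threshold: float = 0.5,
                  ip_threshold: float = 0.0005,
                  sigmas: Sequence[float] = (2.0, 3.0, 4.0, 6.0)):
    """Detect spine centers on a MIP: candidates → classify → NMS.

    Returns a list of ``(row, col, confidence)``, row-major ordered.
    """
    if not hasattr(classifier, "layers_"):
        raise ParameterError("classifier is not fitted")
    if SPINE_CLASS not in classifier.classes_:
        raise ParameterError("classifier has no spine class")
    points = detect_interest_points(mip, threshold=ip_threshold, sigmas=sigmas)
    if not points:
        return []
    patches = np.stack([extract_patch(mip, (p.row, p.col), patch_um).pixels
                        for p in points])
    proba = classifier.predict_proba(patches)
    spine_col = int(np.searchsorted(classifier.classes_, SPINE_CLASS))
    conf = proba[:, spine_col]
    is_spine = (proba.argmax(axis=1) == spine_col) & (conf >= confidence_threshold)
    idx = np.flatnonzero(is_spine)
    if idx.size == 0:
        return []
    rows = np.array([points[i].row for i in idx])
    cols = np.array([points[i].col for i in idx])
    confs = conf[idx]
    radius_px = nms_radius_um / mip.geometry.dx
    kept = _nms(rows, cols, confs, radius_px)
    return [(int(rows[j]), int(cols[j]), float(confs[j])) for j in kept]


def count_spines_timeseries(series, classifier: PatchClassifier,
                            median_window: int = 3, **detect_kwargs):
    """Per-time-point spine counts on a registered series.

    ``series`` may be a :class:`TimeSeries` or a list of :class:`Image2D`
    frames; each frame's MIP is median-filtered before detection.
    """
    frames = series.stacks if isinstance(series, TimeSeries) else series
    counts = []
    for f in frames:
        mip = max_intensity_projection(f) if not isinstance(f, Image2D) else f
        filtered = median_filter2d(mip, median_window)
        counts.append(len(detect_spines(filtered, classifier, **detect_kwargs)))
    return np.asarray(counts, dtype=int)
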