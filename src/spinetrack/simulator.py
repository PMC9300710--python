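"""Synthetic dendrite generator with ground truth.

Emulates in-vivo-like two-photon frames of a single dendrite in the optical
plane: potential synapse sites are placed by a Poisson process along the
dendrite (expected density 2.56 μm⁻¹), each site toggles between occupied
("on") and vacant by an independent two-state Markov chain (per-step
probabilities p_on = 1×10⁻³, p_off = 4.1×10⁻³ over 2000 steps), and the
chain is sampled at 26 evenly spaced keyframes.  Frames are 512×512 at
72 nm/pixel; the dendritic shaft is painted at 1000±100, spines at 2000±300,
values clipped to [0, 2000], blurred with a Gaussian PSF of 600 nm FWHM,
then subjected to Poisson shot noise.

A 3D phantom builder (sphere head + cylinder neck + tube dendrite, optional
Euclidean-nearer distractor tube) extends the same intensity model to
z-stacks for registration and neck-path validation.

Every routine takes or derives a :class:`numpy.random.Generator`; all outputs
are bit-reproducible from the run seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import interpolate, ndimage

from .errors import ParameterError, ShapeError
from .imgio import Image2D, TimeSeries, VoxelGeometry, ZStack

_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class TurnoverParams:
    """Two-state Markov spine turnover (per-step probabilities)."""

    p_on: float = 1e-3
    p_off: float = 4.1e-3
    steps: int = 2000
    n_keyframes: int = 26

    def __post_init__(self):
        if not (0 <= self.p_on <= 1 and 0 <= self.p_off <= 1):
            raise ParameterError("p_on, p_off must be probabilities")
        if self.steps < 1:
            raise ParameterError("steps must be >= 1")

    @property
    def stationary_on_fraction(self) -> float:
        if self.p_on + self.p_off == 0:
            return 0.0
        return self.p_on / (self.p_on + self.p_off)


@dataclass(frozen=True)
class RenderParams:
    """Photometric and geometric rendering model."""

    image_px: int = 512
    pixel_nm: float = 72.0
    dendrite_mean: float = 1000.0
    dendrite_sd: float = 100.0
    spine_mean: float = 2000.0
    spine_sd: float = 300.0
    intensity_max: float = 2000.0
    psf_fwhm_nm: float = 600.0
    dendrite_width_um: float = 0.8
    spine_radius_mean_um: float = 0.4
    spine_radius_sd_um: float = 0.1
    spine_radius_floor_um: float = 0.15
    neck_min_um: float = 0.2
    neck_max_um: float = 1.5
    n_boutons: int = 0
    bouton_radius_um: float = 0.3

    @property
    def pixel_um(self) -> float:
        return self.pixel_nm / 1000.0

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_fwhm_nm * _SIGMA_PER_FWHM / self.pixel_nm

    @property
    def geometry(self) -> VoxelGeometry:
        return VoxelGeometry(dx=self.pixel_um, dy=self.pixel_um, bit_depth=12)


DEFAULT_DENSITY_PER_UM = 2.56


# ---------------------------------------------------------------------------
# stochastic skeleton of the simulation

def place_synapses(length_um: float, density_per_um: float = DEFAULT_DENSITY_PER_UM,
                   rng=None) -> np.ndarray:
    """Poisson-place potential synapse sites along a dendrite.

    Count ~ Poisson(density × length); positions uniform on [0, length],
    returned sorted (arclength coordinates in μm).
    """
    if length_um <= 0:
        raise ParameterError("length_um must be positive")
    if density_per_um < 0:
        raise ParameterError("density must be non-negative")
    rng = np.random.default_rng(rng)
    count = rng.poisson(density_per_um * length_um)
    return np.sort(rng.uniform(0.0, length_um, size=count))


def simulate_states(n_synapses: int, params: TurnoverParams, rng=None) -> np.ndarray:
    """Evolve independent two-state chains; returns (n_synapses, steps) of {0,1}.

    The initial state is drawn from the stationary distribution
    p_on/(p_on+p_off), so keyframe statistics are stationary from the start.
    """
    rng = np.random.default_rng(rng)
    states = np.empty((n_synapses, params.steps), dtype=np.uint8)
    if n_synapses == 0:
        return states
    states[:, 0] = rng.random(n_synapses) < params.stationary_on_fraction
    u = rng.random((n_synapses, params.steps - 1))
    for t in range(1, params.steps):
        prev = states[:, t - 1]
        turn_on = (prev == 0) & (u[:, t - 1] < params.p_on)
        turn_off = (prev == 1) & (u[:, t - 1] < params.p_off)
        states[:, t] = np.where(turn_on, 1, np.where(turn_off, 0, prev))
    return states


def keyframe_states(states: np.ndarray, n_keyframes: int) -> np.ndarray:
    """Sample the chain at ⌊steps/(n_keyframes−1)⌋-spaced steps (first and last included)."""
    steps = states.shape[1]
    if n_keyframes < 2:
        raise ParameterError("n_keyframes must be >= 2")
    if n_keyframes > steps:
        raise ParameterError("n_keyframes cannot exceed steps")
    stride = steps // (n_keyframes - 1)
    idx = np.minimum(np.arange(n_keyframes) * stride, steps - 1)
    return states[:, idx]


# ---------------------------------------------------------------------------
# geometry

@dataclass
class DendriteGeometry:
    """A smooth dendrite centerline with per-synapse spine geometry."""

    centerline_px: np.ndarray      # (K, 2) dense (row, col) samples
    arclength_um: np.ndarray       # (K,) cumulative arclength
    normals: np.ndarray            # (K, 2) unit normals
    length_um: float = 0.0
    synapse_s_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    spine_side: np.ndarray = field(default_factory=lambda: np.empty(0))
    spine_radius_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    neck_length_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    in_frame: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def point_at(self, s_um: float) -> np.ndarray:
        k = int(np.searchsorted(self.arclength_um, s_um))
        k = min(k, len(self.arclength_um) - 1)
        return self.centerline_px[k]

    def normal_at(self, s_um: float) -> np.ndarray:
        k = int(np.searchsorted(self.arclength_um, s_um))
        k = min(k, len(self.normals) - 1)
        return self.normals[k]


def make_dendrite_geometry(params: RenderParams, rng=None,
                           n_control: int = 6, jitter_frac: float = 0.08) -> DendriteGeometry:
    """Draw a smooth random centerline spanning the frame left-to-right."""
    rng = np.random.default_rng(rng)
    n = params.image_px
    xs = np.linspace(0.04 * n, 0.96 * n, n_control)
    ys = n / 2.0 + rng.uniform(-jitter_frac * n, jitter_frac * n, size=n_control)
    spline = interpolate.CubicSpline(xs, ys)
    cols = np.linspace(xs[0], xs[-1], 6 * n)
    rows = spline(cols)
    pts = np.column_stack([rows, cols])
    seg = np.diff(pts, axis=0)
    seg_um = np.linalg.norm(seg, axis=1) * params.pixel_um
    s = np.concatenate([[0.0], np.cumsum(seg_um)])
    tangents = np.vstack([seg, seg[-1:]])
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    return DendriteGeometry(centerline_px=pts, arclength_um=s, normals=normals,
                            length_um=float(s[-1]))


def attach_spines(geom: DendriteGeometry, synapse_s_um: np.ndarray,
                  params: RenderParams, rng=None) -> DendriteGeometry:
    """Fix each potential synapse's spine geometry (side, head radius, neck length).

    The geometry is drawn once per simulation so that the same dendrite
    evolves over time; sites whose head would leave the frame are flagged
    out-of-frame and never rendered.
    """
    rng = np.random.default_rng(rng)
    k = len(synapse_s_um)
    side = rng.choice([-1.0, 1.0], size=k)
    radius = np.maximum(rng.normal(params.spine_radius_mean_um,
                                   params.spine_radius_sd_um, size=k),
                        params.spine_radius_floor_um)
    neck = rng.uniform(params.neck_min_um, params.neck_max_um, size=k)
    in_frame = np.empty(k, dtype=bool)
    margin = 2.0
    for i, s in enumerate(synapse_s_um):
        c = _head_center_px(geom, s, side[i], radius[i], neck[i], params)
        r_px = radius[i] / params.pixel_um
        lo = c - r_px - margin
        hi = c + r_px + margin
        in_frame[i] = lo.min() >= 0 and hi.max() < params.image_px
    return replace(geom, synapse_s_um=np.asarray(synapse_s_um), spine_side=side,
                   spine_radius_um=radius, neck_length_um=neck, in_frame=in_frame)


def _head_center_px(geom: DendriteGeometry, s_um: float, side: float,
                    radius_um: float, neck_um: float, params: RenderParams) -> np.ndarray:
    base = geom.point_at(s_um)
    n = geom.normal_at(s_um) * side
    offset_um = params.dendrite_width_um / 2.0 + neck_um + radius_um
    return base + n * (offset_um / params.pixel_um)


def _paint_disc(canvas_mask: np.ndarray, center: np.ndarray, radius_px: float):
    r0 = max(int(np.floor(center[0] - radius_px)) - 1, 0)
    r1 = min(int(np.ceil(center[0] + radius_px)) + 2, canvas_mask.shape[0])
    c0 = max(int(np.floor(center[1] - radius_px)) - 1, 0)
    c1 = min(int(np.ceil(center[1] + radius_px)) + 2, canvas_mask.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px ** 2
    canvas_mask[r0:r1, c0:c1] |= inside


def _paint_segment(canvas_mask: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                   width_px: float = 1.0):
    n = max(int(np.ceil(np.linalg.norm(p1 - p0) * 2)), 2)
    for t in np.linspace(0.0, 1.0, n):
        p = p0 * (1 - t) + p1 * t
        _paint_disc(canvas_mask, p, max(width_px / 2.0, 0.6))


def _dendrite_mask(geom: DendriteGeometry, params: RenderParams) -> np.ndarray:
    n = params.image_px
    raster = np.zeros((n, n), dtype=bool)
    pts = np.round(geom.centerline_px).astype(int)
    ok = (pts[:, 0] >= 0) & (pts[:, 0] < n) & (pts[:, 1] >= 0) & (pts[:, 1] < n)
    raster[pts[ok, 0], pts[ok, 1]] = True
    dist = ndimage.distance_transform_edt(~raster)
    return dist <= params.dendrite_width_um / 2.0 / params.pixel_um


def render_frame(geom: DendriteGeometry, on_mask: np.ndarray,
                 params: RenderParams, rng=None, noise: bool = True,
                 gamma: float = 1.0):
    """Render one keyframe: paint → clip-scale → PSF blur → Poisson noise.

    ``on_mask`` is a boolean vector over the geometry's synapse sites.
    ``gamma`` scales the photon budget of the shot noise (γ>1: cleaner).
    Returns ``(Image2D, ground_truth dict)`` where the ground truth holds the
    noiseless dendrite/spine masks and on-spine centers.
    """
    rng = np.random.default_rng(rng)
    n = params.image_px
    on_mask = np.asarray(on_mask, dtype=bool)
    if on_mask.shape != geom.synapse_s_um.shape:
        raise ShapeError("on_mask must align with the geometry's synapse sites")

    dend = _dendrite_mask(geom, params)
    spine_labels = np.zeros((n, n), dtype=np.int32)
    spine_any = np.zeros((n, n), dtype=bool)
    centers, radii, label_ids = [], [], []
    label = 0
    for i in np.flatnonzero(on_mask & geom.in_frame):
        label += 1
        s = geom.synapse_s_um[i]
        center = _head_center_px(geom, s, geom.spine_side[i],
                                 geom.spine_radius_um[i], geom.neck_length_um[i], params)
        r_px = geom.spine_radius_um[i] / params.pixel_um
        head = np.zeros((n, n), dtype=bool)
        _paint_disc(head, center, r_px)
        base = geom.point_at(s)
        neckm = np.zeros((n, n), dtype=bool)
        _paint_segment(neckm, base, center, width_px=1.0)
        spine_labels[head & (spine_labels == 0)] = label
        spine_any |= head | neckm
        centers.append(center)
        radii.append(geom.spine_radius_um[i])
        label_ids.append(int(i))

    boutons = np.zeros((n, n), dtype=bool)
    for _ in range(params.n_boutons):
        for _attempt in range(50):
            c = rng.uniform(0.1 * n, 0.9 * n, size=2)
            if not dend[int(c[0]), int(c[1])] and not spine_any[int(c[0]), int(c[1])]:
                _paint_disc(boutons, c, params.bouton_radius_um / params.pixel_um)
                break

    img = np.zeros((n, n), dtype=float)
    img[dend] = rng.normal(params.dendrite_mean, params.dendrite_sd, size=int(dend.sum()))
    bright = spine_any | boutons
    img[bright] = rng.normal(params.spine_mean, params.spine_sd, size=int(bright.sum()))
    img = np.clip(img, 0.0, params.intensity_max)
    img = ndimage.gaussian_filter(img, params.psf_sigma_px)
    noiseless = img.copy()
    if noise:
        img = rng.poisson(np.clip(img, 0, None) * gamma).astype(float) / gamma

    truth = {
        "dendrite_mask": dend,
        "spine_labels": spine_labels,
        "spine_mask": spine_labels > 0,
        "neck_and_head_mask": spine_any,
        "bouton_mask": boutons,
        "centers_px": np.asarray(centers, dtype=float).reshape(-1, 2),
        "radii_um": np.asarray(radii, dtype=float),
        "synapse_index": np.asarray(label_ids, dtype=int),
        "noiseless": noiseless,
    }
    return Image2D(img, params.geometry), truth


@dataclass
class SimulatedDendrite:
    """A rendered time series plus the full generating ground truth."""

    geometry: DendriteGeometry
    turnover: TurnoverParams
    render: RenderParams
    states: np.ndarray          # (n_synapses, steps)
    keyframes: np.ndarray       # (n_synapses, n_keyframes)
    frames: list                # Image2D per keyframe
    truths: list                # ground-truth dict per keyframe
    days: np.ndarray            # reporting label only

    @property
    def true_counts(self) -> np.ndarray:
        """Number of rendered (in-frame, on) spines at each keyframe."""
        in_frame = self.geometry.in_frame[:, None]
        return (self.keyframes.astype(bool) & in_frame).sum(axis=0)

    def as_timeseries(self) -> TimeSeries:
        stacks = [ZStack(f.data[:, :, None], f.geometry) for f in self.frames]
        return TimeSeries(stacks, list(self.days))


def simulate_timeseries(length_um: float = 30.0,
                        density_per_um: float = DEFAULT_DENSITY_PER_UM,
                        turnover: Optional[TurnoverParams] = None,
                        render: Optional[RenderParams] = None,
                        seed=None, noise: bool = True,
                        gamma: float = 1.0,
                        total_days: float = 75.0) -> SimulatedDendrite:
    """Compose the full simulation; bit-reproducible from ``seed``.

    The requested ``length_um`` bounds the synapse-bearing portion of the
    centerline (the drawn curve may be longer; extra length carries no sites).
    """
    turnover = turnover or TurnoverParams()
    render = render or RenderParams()
    root = np.random.SeedSequence(seed)
    s_geom, s_place, s_attach, s_states, s_frames = root.spawn(5)

    geom = make_dendrite_geometry(render, np.random.default_rng(s_geom))
    usable = min(length_um, geom.length_um)
    positions = place_synapses(usable, density_per_um, np.random.default_rng(s_place))
    geom = attach_spines(geom, positions, render, np.random.default_rng(s_attach))
    states = simulate_states(len(positions), turnover, np.random.default_rng(s_states))
    keyframes = keyframe_states(states, turnover.n_keyframes)

    frame_seeds = s_frames.spawn(turnover.n_keyframes)
    frames, truths = [], []
    for k in range(turnover.n_keyframes):
        img, truth = render_frame(geom, keyframes[:, k].astype(bool), render,
                                  np.random.default_rng(frame_seeds[k]),
                                  noise=noise, gamma=gamma)
        frames.append(img)
        truths.append(truth)
    days = total_days * np.arange(turnover.n_keyframes) / (turnover.n_keyframes - 1)
    return SimulatedDendrite(geometry=geom, turnover=turnover, render=render,
                             states=states, keyframes=keyframes, frames=frames,
                             truths=truths, days=days)


# ---------------------------------------------------------------------------
# 3D phantom

def make_phantom_zstack(head_radius_um: float = 0.4,
                        neck_length_um: float = 1.0,
                        neck_tilt_deg: float = 0.0,
                        dendrite_radius_um: float = 0.4,
                        distractor_gap_um: Optional[float] = None,
                        shape=(64, 96, 16),
                        geometry: Optional[VoxelGeometry] = None,
                        render: Optional[RenderParams] = None,
                        seed=None, noise: bool = False, gamma: float = 1.0):
    """Render a 3D spine phantom: sphere head + cylinder neck + tube dendrite.

    The dendrite runs along the column axis through the mid-plane; the head
    sits a gap of ``neck_length_um`` above the dendrite surface, connected by
    a straight neck tilted ``neck_tilt_deg`` from the surface normal.  When
    ``distractor_gap_um`` is given, a second, disconnected tube is placed on
    the opposite side of the head with its *surface* that much from the head
    center — nearer in Euclidean terms than the parent dendrite, but not
    intensity-connected to the head.

    Returns ``(ZStack, ground_truth dict)`` with the true neck length, the
    head center voxel, and all masks.
    """
    render = render or RenderParams()
    geometry = geometry or VoxelGeometry(dx=0.072, dy=0.072, dz=0.2, bit_depth=12)
    rng = np.random.default_rng(seed)
    m, n, z = shape
    dxy, dz = geometry.dx, geometry.dz
    rr, cc, zz = np.mgrid[0:m, 0:n, 0:z]
    # physical coordinates in μm
    y = rr * dxy
    x = cc * dxy
    w = zz * dz

    dend_row = 0.72 * m * dxy
    dend_z = (z // 2) * dz
    dend = (y - dend_row) ** 2 + (w - dend_z) ** 2 <= dendrite_radius_um ** 2

    tilt = np.deg2rad(neck_tilt_deg)
    direction = np.array([-np.cos(tilt), np.sin(tilt), 0.0])  # (y, x, z), toward smaller row
    base_col = 0.5 * n * dxy
    surface = np.array([dend_row - dendrite_radius_um * np.cos(tilt),
                        base_col + dendrite_radius_um * np.sin(tilt), dend_z])
    head_c = surface + direction * (neck_length_um + head_radius_um)
    if neck_length_um < 0:
        raise ParameterError("neck length cannot be negative")
    if head_c[0] - head_radius_um < 0:
        raise ParameterError("phantom head leaves the volume; enlarge shape")

    head = ((y - head_c[0]) ** 2 + (x - head_c[1]) ** 2 + (w - head_c[2]) ** 2
            <= head_radius_um ** 2)
    if np.any(head & dend) and neck_length_um > 0:
        raise ParameterError("head overlaps dendrite beyond tangency")

    # neck cylinder between the two surfaces
    p0, p1 = surface, surface + direction * neck_length_um
    seg = p1 - p0
    seg_len2 = max(float(seg @ seg), 1e-12)
    py = y - p0[0]
    px = x - p0[1]
    pz = w - p0[2]
    t = np.clip((py * seg[0] + px * seg[1] + pz * seg[2]) / seg_len2, 0.0, 1.0)
    d2 = ((py - t * seg[0]) ** 2 + (px - t * seg[1]) ** 2 + (pz - t * seg[2]) ** 2)
    neck_r = max(0.5 * head_radius_um, 1.2 * dxy)
    neck = (d2 <= neck_r ** 2) if neck_length_um > 0 else np.zeros_like(dend)

    distractor = np.zeros_like(dend)
    if distractor_gap_um is not None:
        dist_radius = dendrite_radius_um
        dist_row = head_c[0] - (distractor_gap_um + dist_radius)
        if dist_row - dist_radius < 0:
            raise ParameterError("distractor leaves the volume; enlarge shape")
        distractor = (y - dist_row) ** 2 + (w - dend_z) ** 2 <= dist_radius ** 2

    img = np.zeros(shape, dtype=float)
    img[dend | distractor] = rng.normal(render.dendrite_mean, render.dendrite_sd,
                                        size=int((dend | distractor).sum()))
    bright = head | neck
    img[bright] = rng.normal(render.spine_mean, render.spine_sd, size=int(bright.sum()))
    img = np.clip(img, 0.0, render.intensity_max)
    sigma_vox = (render.psf_fwhm_nm * _SIGMA_PER_FWHM / 1000.0 / dxy,
                 render.psf_fwhm_nm * _SIGMA_PER_FWHM / 1000.0 / dxy,
                 render.psf_fwhm_nm * _SIGMA_PER_FWHM / 1000.0 / dz)
    img = ndimage.gaussian_filter(img, sigma_vox)
    if noise:
        img = rng.poisson(np.clip(img, 0, None) * gamma).astype(float) / gamma

    head_center_vox = np.array([head_c[0] / dxy, head_c[1] / dxy, head_c[2] / dz])
    truth = {
        "neck_length_um": float(neck_length_um),
        "head_center_vox": head_center_vox,
        "head_center_um": head_c,
        "head_mask": head,
        "neck_mask": neck,
        "dendrite_mask": dend,
        "distractor_mask": distractor,
        "dendrite_axis_row_um": dend_row,
        "surface_point_um": surface,
    }
    return ZStack(img, geometry), truth


# ---------------------------------------------------------------------------
# labeled patches for classifier training

#: class labels: 1 spine head, 2 overlapping spines, 3 head–dendrite junction,
#: 4 dendrite edge, 5 dendrite interior, 6 neck midpoint, 7 head boundary,
#: 8 bouton/axon, 9 background noise
PATCH_CLASS_NAMES = {
    1: "spine head", 2: "multiple overlapping spines",
    3: "spine-dendrite junction", 4: "dendrite edge", 5: "dendrite",
    6: "spine neck", 7: "spine head edge", 8: "bouton/axon", 9: "noise",
}


def _class_sites(sim: SimulatedDendrite, k: int) -> dict:
    """Candidate patch centers (row, col) per class for keyframe ``k``."""
    geom, params = sim.geometry, sim.render
    truth = sim.truths[k]
    on = sim.keyframes[:, k].astype(bool) & geom.in_frame
    on_idx = np.flatnonzero(on)
    sites = {c: [] for c in PATCH_CLASS_NAMES}

    centers = {i: _head_center_px(geom, geom.synapse_s_um[i], geom.spine_side[i],
                                  geom.spine_radius_um[i], geom.neck_length_um[i],
                                  params)
               for i in on_idx}
    for i in on_idx:
        c = centers[i]
        base = geom.point_at(geom.synapse_s_um[i])
        sites[1].append(c)
        sites[3].append(base + (c - base) * (params.dendrite_width_um / 2.0
                        / max(np.linalg.norm(c - base) * params.pixel_um, 1e-9)))
        sites[6].append((base + c) / 2.0)
        r_px = geom.spine_radius_um[i] / params.pixel_um
        sites[7].append(c + np.array([0.0, r_px]))
    # class 2 only for heads that genuinely overlap in the projection
    for a in range(len(on_idx)):
        for b in range(a + 1, len(on_idx)):
            ia, ib = on_idx[a], on_idx[b]
            ca, cb = centers[ia], centers[ib]
            touch_um = geom.spine_radius_um[ia] + geom.spine_radius_um[ib] + 0.1
            if np.linalg.norm(ca - cb) * params.pixel_um < touch_um:
                sites[2].append((ca + cb) / 2.0)

    dend = truth["dendrite_mask"]
    edge = dend & ~ndimage.binary_erosion(dend)
    er, ec = np.nonzero(edge)
    sites[4] = list(np.column_stack([er, ec]).astype(float))
    axis_pts = geom.centerline_px[::40]
    sites[5] = [p for p in axis_pts
                if 0 <= p[0] < params.image_px and 0 <= p[1] < params.image_px
                and dend[int(p[0]), int(p[1])]]
    blabels, nb = ndimage.label(truth["bouton_mask"])
    for b in range(1, nb + 1):
        br, bc = np.nonzero(blabels == b)
        sites[8].append(np.array([br.mean(), bc.mean()]))
    fg = dend | truth["neck_and_head_mask"] | truth["bouton_mask"]
    far = ndimage.distance_transform_edt(~fg) > 25
    fr, fc = np.nonzero(far)
    sites[9] = list(np.column_stack([fr, fc]).astype(float))
    return sites


def patch_training_set(sim: SimulatedDendrite, n_per_class: int = 200,
                       patch_um: float = 3.4, seed=None):
    """Sample labeled patches from the simulation's ground-truth geometry.

    Returns ``(patches, labels)`` where patches is an (n, side, side) float
    array and labels the 1-based class vector.  Classes with no available
    sites are omitted (with fewer samples the set is truncated, not padded).
    """
    from .detection import extract_patch  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    pooled = {c: [] for c in PATCH_CLASS_NAMES}
    for k in range(len(sim.frames)):
        for c, pts in _class_sites(sim, k).items():
            pooled[c].extend((k, p) for p in pts)

    patches, labels = [], []
    side_ref = None
    for c in sorted(pooled):
        entries = pooled[c]
        if not entries:
            continue
        take = min(n_per_class, len(entries))
        chosen = rng.choice(len(entries), size=take, replace=False)
        for j in chosen:
            k, p = entries[j]
            center = (int(round(p[0])), int(round(p[1])))
            patch = extract_patch(sim.frames[k], center, patch_um)
            if side_ref is None:
                side_ref = patch.pixels.shape[0]
            patches.append(patch.pixels)
            labels.append(c)
    return np.asarray(patches, dtype=float), np.asarray(labels, dtype=int)
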