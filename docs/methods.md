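# Methods

This note records the models, numerical choices and limitations behind
`spinetrack`, in the spirit of the methods documentation of packages like
scanpy or msprime.

## Image model and containers

A z-stack is an `(M, N, Z)` array of non-negative intensities with physical
sampling carried by `VoxelGeometry` (μm per pixel/slice; 12-bit data lives in
16-bit containers and the configured bit depth wins over the container
depth). All 2D analysis runs on maximum-intensity projections (MIPs),
median-filtered with an edge-replicating window (default 3 px at ≥0.03 μm/px
sampling, 5 px for finer sampling; edge replication avoids the dark border
halo that would bias Otsu thresholds).

## Registration

Global drift between consecutive time points is estimated on MIPs by
phase cross-correlation with matrix-multiply DFT upsampling (default 1/100
px; `skimage.registration.phase_cross_correlation`) and applied once as a
Fourier-domain translation. Chaining registers each time point to its
(already registered) predecessor, so the per-step estimate is the full
accumulated drift and every stack is resampled exactly once. An integer
z-offset is chosen by maximizing slice-wise correlation after lateral
alignment; subvoxel z is deliberately not pursued since all downstream 2D
analysis uses MIPs. Wrap-around artifacts from the periodic Fourier shift
are confined to a ~5 px border which should be excluded from histogram
statistics.

Local re-centering of a spine's ROI maximizes the normalized mutual
information NMI = (H(A)+H(B))/H(A,B) ∈ [1, 2] (64-bin joint histogram of
range-standardized crops; a constant pair is assigned the perfect-dependence
limit 2) over all integer offsets within a Chebyshev radius (default 10 px
— the search neighborhood size is a free parameter of the design; ties break
toward the smallest offset). An exhaustive search is cheap at these sizes
and exactly matches its own oracle.

## Detection

Candidate locations are local maxima of a multi-scale determinant-of-Hessian
response on the range-normalized MIP (σ ∈ {2, 3, 4, 6} px by default). This
is the interest-point stage that SURF-type detectors build on; descriptors
are never used, only locations, so the patent-encumbered descriptor pipeline
is unnecessary. Patches of fixed physical side 3.4 μm (rounded to an odd
pixel count: 97 px at 0.035 μm/px, 47 px at 0.072 μm/px) are cropped with
zero padding; physical size, not pixel count, is authoritative because pixel
sizes vary across datasets.

The patch classifier is a CNN with six blocks of 3×3 convolution → batch
normalization → swish → 2×2 ceil-mode max pooling (default widths
16/32/48/64/96/128), then fully connected layers 4096 → 256 → n_classes.
It is implemented directly in numpy (shifted-view convolutions, exact
hand-derived gradients validated against numerical differentiation, Adam,
class-weighted cross-entropy) and follows the scikit-learn estimator
protocol. Patches are standardized per-sample, which makes classification
invariant to global intensity scale. Training holds out 30% for validation
and keeps the best-validation-accuracy checkpoint. A `small()` profile
(widths 8/12/16/16/24/24, FC 256/64) trains in about a minute on one CPU and
is used throughout the tests; the full-width profile is the default for real
data. Class labels (spine head, overlapping spines, head–dendrite junction,
dendrite edge, dendrite, neck, head edge, bouton/axon, noise) are sampled
from the simulator's generative geometry; a two-class mode collapses classes
2–9 for low-SNR (in-vivo-like) data. Detections are class-1 candidates above
confidence 0.5, merged by non-maximum suppression within 0.5 μm.

## Dendrite segmentation

Median filter → Otsu threshold (256-bin between-class-variance maximization;
when the criterion is flat across an empty intensity gap all maximizing bins
are averaged, placing the threshold mid-gap) → largest connected component →
skeletonization. The medial axis is the skeleton's diameter path (double
breadth-first search between the two farthest skeleton points — the paper's
"two ends of the dendrite" made concrete). At each axis point the Euclidean
distance transform gives a local radius, clamped to the median radius ±25%
(the tolerance quantifying "diameter remains constant"); the union of disks
is the shaft mask, which removes spines because their protrusions exceed the
clamped radius. The median shaft intensity is recorded as the IFI
normalizer. Boundary correction (`adjust_boundary`) is a morphological curve
evolution — signed dilation/erosion with majority-vote curvature smoothing
and an optional intensity floor that forbids growth into pixels below a
level; the default is purely geometric so that growth is strictly monotone.

## Spine-head segmentation

Seeds are the h-maxima regions of the ROI (h = 10% of the ROI dynamic range
by default) united with a one-pixel seed at the detected center (which
guarantees a seed even on flat ROIs). Watershed runs on the inverted
intensity relief inside the connected Otsu foreground around the center; a
spine entirely below threshold instead receives a circular mock boundary of
radius 0.6 μm (a typical head radius) and is flagged as such. The watershed
region is then refined: pixels are over-clustered (connectivity-constrained
Ward, up to 30 clusters, on per-region-standardized intensity and geodesic
distance-to-seed), merged to at most 10 clusters, ranked by mean distance
from the seed, and accumulated inward-out until the next cluster's mean
intensity drops below f = 0.5 of the seed cluster's mean. The result always
contains the seed, is one connected component, and is a subset of the
watershed region. Because Otsu, h-maxima and the cluster criterion are all
defined relative to the ROI's own histogram, the segmentation is invariant
to global intensity rescaling — the mechanism behind the pipeline's
laser-power robustness, asserted in the tests at scales 0.25–1.0 with
Dice ≥ 0.95.

## Neck path

Each z-slice of the volume is grey-eroded by a disk (default radius 1 px) to
suppress thin spurious bridges; the eroded intensities, normalized by the
*raw* maximum (so erosion genuinely lowers thin structures) and floored at
ε = 10⁻³, form the speed map. Arrival times from the head center solve the
eikonal equation |∇T| = 1/speed.

The solver runs in two stages: (1) a Dijkstra-style geometric marching on
the 26-neighbor graph (`skimage.graph.MCP_Geometric`) provides an upper
bound and a causal ordering; (2) voxels are revisited in that order, in
bands, and reassigned once from upwind second-order one-sided differences
over multiple rotated stencils (axis-aligned plus plane-diagonal stencils
wherever in-plane spacings are equal). The ordered single-assignment pass is
essential: naive fixed-point iteration of the same second-order operator is
unstable under monotone min-updates (extrapolation undershoots lock in and
propagate). A ball of 5 voxel spacings around the source is initialized
with the exact local distance, removing the point-source rarefaction error.
On a uniform-speed 21³ grid the maximum relative error against the Euclidean
distance is ≈1.5%; against a 26-neighbor Dijkstra oracle the deviation is
bounded by the graph metric's chamfer discretization error (8.24% in-plane,
12.81% in 3D — the worst directions being (2,1)- and (2,1,1)-like).

Candidate neck geodesics are traced by 4th-order Runge–Kutta descent (step
0.25 voxel) on the arrival-time field from the N = 8 dendrite-perimeter
voxels nearest the head center (anisotropy-aware Euclidean metric,
deterministic row/col/slice tie-breaks). For gradient evaluation the field
is capped at the start's arrival time — later-arriving voxels are never on
the geodesic, and their enormous values would otherwise dominate
interpolated gradients at slow/fast interfaces; a discrete neighbor-descent
fallback guarantees progress if the continuous gradient stalls. Each
candidate path is resampled to uniform 0.5-voxel arclength (making the
discrete derivatives step-size independent) and scored by physical length L
(μm), complexity C = Σ|Δx|+|Δy|+|Δz| (voxel units), and smoothness
S = Σ|I(p_{k+1})−I(p_k)| (trilinear samples). S is the total intensity
variation along the path: a raw sum of intensities would perversely
penalize bright, well-resolved necks, so the derivative reading of the
smoothness term is used. The selected path minimizes the sum of the three
max-normalized terms; it is then trimmed to the longest contiguous run
outside both the head and dendrite masks, terms are recomputed on the
trimmed portion (the alternative — trimming after scoring but reporting
pre-trim terms — would let head-interior detours distort the neck length),
and the trimmed L is the neck length. A head touching the shaft yields
length 0 with a `zero-length` flag rather than an error.

## Volume estimation

IFI: raw_sum = Σ intensities in the head mask; background = (minimum
intensity in the spine's ROI window) × mask area — per-ROI, not per-frame,
since the shared frame minimum would couple distant spines; normalized
volume = (raw_sum − background)/median shaft intensity. A negative numerator
(noise-dominated time point) clamps to 0 with a flag so longitudinal runs
complete. The statistic is homogeneous of degree zero in intensity.

FWHM: intensities are sampled by cubic-spline interpolation along a line
through the head center at an explicit, analyst-chosen orientation (the
PSD-parallel direction is not searched automatically), fitted by least
squares to a Gaussian plus constant offset (the offset absorbs nonzero
background). FWHM = 2√(2 ln 2)·σ is the sphere diameter; volume = 4/3·π·r³
in μm³. Fits whose σ exceeds half the line length are rejected as
non-convergent.

Trend agreement: sMAPE = 100·(1/t)·Σ|aᵢ−bᵢ|/|aᵢ+bᵢ| (a both-zero term
contributes zero; a conflicting zero-sum pair is an input error) and
SS = 100 − sMAPE. The alternative literal composition of the two printed
formulas (100·(1−sMAPE) with sMAPE already in percent) would produce scores
like −2400 and is inconsistent with reported score magnitudes near 90–97,
so the percent-scale difference is implemented.

## Simulator

The generator renders what the tests measure, and its defaults are the study
conditions: 512×512 frames at 72 nm/px; a single in-plane dendrite drawn as
a cubic spline through jittered control points (width 0.8 μm); potential
synapses placed by a Poisson process at 2.56 μm⁻¹; independent two-state
Markov chains per site (p_on = 1×10⁻³, p_off = 4.1×10⁻³ per step, 2000
steps, initialized from the stationary distribution
p_on/(p_on+p_off) ≈ 0.196) sampled at 26 keyframes (⌊steps/25⌋-spaced,
labeled in days over 75 for reporting only); heads as discs of radius
N(0.4, 0.1) μm floored at 0.15 μm, necks 1 px wide with gap U(0.2, 1.5) μm,
geometry fixed once per simulation so the same dendrite evolves. Rendering
paints dendrite pixels N(1000, 100) and spine pixels N(2000, 300), clips to
[0, 2000], convolves with a Gaussian PSF of 600 nm FWHM
(σ ≈ 254.8 nm ≈ 3.54 px) and applies Poisson noise last (shot noise
physically follows the optics); a photon-budget multiplier γ scales the
noise level (γ = 4 is the "low-noise" condition in the tests). Head and
neck shape, dendrite curvature and the bouton distractors are this
package's own geometric stand-ins — the original simulation code is not
redistributed — and all of their parameters are exposed.

A 3D phantom (sphere head + tilted cylinder neck + tube dendrite, optional
parallel distractor tube placed nearer the head in Euclidean terms but not
intensity-connected) extends the same photometric model to z-stacks for
registration and neck-path validation; its neck length is exact by
construction.

What the simulator does not emulate: non-translational motion, depth-
dependent PSF and scattering, out-of-plane dendrites and z-projection
artifacts from crossing processes, photobleaching trends, biological shape
irregularity of heads and necks, and real annotation noise. Tests passing
against it therefore validate the algorithmic contracts and parameter
recovery, not performance on real tissue; the classifier in particular is
trained on simulator geometry and would need retraining on annotated
microscopy for real use.

## Pipeline and determinism

`run_pipeline` composes load → chained global registration → MIP + median
filter → detection at t = 0 (or user-supplied centers) → per-time-point
dendrite segmentation → per-spine local registration, head segmentation,
IFI (FWHM when an orientation is given), neck extraction on 3D data →
CSV/TIFF/JSON export. Spine identity is fixed by the t = 0 detections and
propagated by local registration; a `redetect` mode exists for turnover
studies. Per-spine failures degrade to flags (`missing`, `mock`,
`ifi-clamped`, `zero-neck`, …) so runs complete; missing time points export
as empty cells, never zeros. All randomness flows from explicit seeds
(numpy `SeedSequence` spawning), and rerunning a configuration reproduces
byte-identical CSVs.

Problem sizes in the test suite (20 frames for segmentation accuracy, 10
neck phantoms, five series for count tracking, the `small()` classifier
profile) were chosen to keep the whole suite at a few minutes on one CPU
while leaving the acceptance margins wide.

## Known limitations

- The classifier architecture is faithful to its specification, but the
  shipped training route uses simulated patches; no pretrained weights for
  real microscopy are included.
- The neck tracer assumes the head center and parent dendrite lie in the
  imaged volume; necks leaving the stack axially are foreshortened.
- `adjust_boundary` is a programmatic correction hook, not an interactive
  editor; its evolution is geometric unless an intensity floor is given.
- Only translational registration is implemented; rotation or deformation
  of the field of view is out of scope.
- TIFF is the only supported container; vendor formats must be converted
  upstream.
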