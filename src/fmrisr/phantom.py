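"""Synthetic phantom generator with known ground truth.

Emulates the study conditions the pipeline is built for: a pair of
static structural slice stacks at 128x128 and 64x64 related by a known
downsampling operator, and a 900-volume, TR = 0.5 s, 64x64 BOLD series
containing two spatially adjacent, partially overlapping elliptical
active regions (the "thumb" and "little finger" motor patches).  Each
active voxel carries a percent-signal-change response — an on/off
boxcar convolved with the canonical HRF — on top of a tissue-like
baseline, plus linear drift, i.i.d. Gaussian noise, and a structured
(spatially smooth, temporally slow, low-rank) noise component standing
in for physiological fluctuations.  The noisy
high-resolution frames are block-averaged 2x2 to produce the
low-resolution series actually handed to the pipeline, so the HR -> LR
relationship is exactly known.

No physical MR simulation is attempted (no T2* decay, k-space, motion
or physiological noise); the phantom's job is to make every downstream
stage testable against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
from scipy import ndimage, optimize

from .hrf import canonical_hrf
from .io import FunctionalSeries, StructuralImage, TaskDesign

__all__ = [
    "EllipseGeometry",
    "PhantomSpec",
    "GroundTruth",
    "block_average",
    "downsample_mask",
    "make_structural_pair",
    "make_functional_series",
    "default_task_design",
    "separability_spec",
    "recovery_spec",
    "hr_series",
    "region_masks",
    "task_responses",
    "TASK_A",
    "TASK_B",
]

TASK_A = "thumb"
TASK_B = "little_finger"


@dataclass(frozen=True)
class EllipseGeometry:
    """Axis-aligned ellipse in high-res pixel coordinates."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]

    def rasterize(self, grid: int) -> np.ndarray:
        x = np.arange(grid)[:, None] + 0.5
        y = np.arange(grid)[None, :] + 0.5
        cx, cy = self.center
        a, b = self.semi_axes
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0


def _default_region(which: str) -> EllipseGeometry:
    # Centres are placeholders: region_masks repositions them
    # symmetrically along the joining line to honour overlap_fraction.
    if which == "a":
        return EllipseGeometry(center=(56.0, 64.0), semi_axes=(5.0, 3.5))
    return EllipseGeometry(center=(72.0, 64.0), semi_axes=(5.0, 3.5))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic acquisition.

    ``signal_amplitude`` is the fractional BOLD signal change at the HRF
    peak (0.03 = 3%).  ``noise_sd`` is the Gaussian noise sd in
    intensity units *on the high-res grid*; 2x2 block averaging halves
    it on the low-res grid.  ``drift_slope`` is intensity units per
    volume.  ``overlap_fraction`` is the target |A ∩ B| / |A| of the two
    region masks; centre separation is solved from it.
    """

    grid_hr: int = 128
    scale: int = 2
    n_volumes: int = 900
    tr: float = 0.5
    n_slices_structural: int = 30
    region_a_geometry: EllipseGeometry = field(default_factory=lambda: _default_region("a"))
    region_b_geometry: EllipseGeometry = field(default_factory=lambda: _default_region("b"))
    overlap_fraction: float | None = 0.45
    baseline_mean: float = 500.0
    signal_amplitude: float = 0.03
    noise_sd: float = 5.0
    structured_noise_sd: float = 10.0
    structured_noise_rank: int = 64
    structured_noise_scale: float = 4.0
    structured_noise_cutoff: float = 0.08
    drift_slope: float = 0.02
    analysis_mask_dilation: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale < 1:
            raise ValueError("scale must be >= 1")
        if self.grid_hr % self.scale != 0:
            raise ValueError("grid_hr must be divisible by scale")
        if self.overlap_fraction is not None and not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.n_volumes < 1 or self.tr <= 0:
            raise ValueError("n_volumes and tr must be positive")
        if self.noise_sd < 0 or self.structured_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @property
    def grid_lr(self) -> int:
        return self.grid_hr // self.scale


@dataclass(frozen=True)
class GroundTruth:
    """Everything the phantom knows that a real study would not."""

    mask_a_hr: np.ndarray
    mask_b_hr: np.ndarray
    analysis_mask_hr: np.ndarray
    downsample_operator: str
    clean_series_hr: np.ndarray
    noisy_series_hr: np.ndarray
    response_a: np.ndarray
    response_b: np.ndarray

    @property
    def mask_a_lr(self) -> np.ndarray:
        return downsample_mask(self.mask_a_hr, self._scale())

    @property
    def mask_b_lr(self) -> np.ndarray:
        return downsample_mask(self.mask_b_hr, self._scale())

    @property
    def analysis_mask_lr(self) -> np.ndarray:
        return downsample_mask(self.analysis_mask_hr, self._scale())

    def _scale(self) -> int:
        # encoded in the operator string, e.g. "block_average_2x2"
        return int(self.downsample_operator.rsplit("_", 1)[-1].split("x")[0])


def block_average(image: np.ndarray, scale: int) -> np.ndarray:
    """Exact ``scale x scale`` block mean over the two leading axes.

    Preserves the global mean of every frame exactly (each HR pixel
    contributes 1/scale^2 to exactly one LR pixel).
    """
    if scale == 1:
        return image.copy()
    h, w = image.shape[:2]
    if h % scale or w % scale:
        raise ValueError("image sides must be divisible by the block size")
    shaped = image.reshape((h // scale, scale, w // scale, scale) + image.shape[2:])
    return shaped.mean(axis=(1, 3))


def downsample_mask(mask_hr: np.ndarray, scale: int) -> np.ndarray:
    """Majority-vote (block fraction >= 0.5) LR rendering of an HR mask."""
    return block_average(mask_hr.astype(float), scale) >= 0.5


def _tissue_image(grid: int, n_slices: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth tissue-like contrast: Gaussian blobs + an elliptical 'head' edge."""
    x = np.arange(grid)[:, None] + 0.5
    y = np.arange(grid)[None, :] + 0.5
    c = grid / 2.0
    head = ((x - c) / (0.46 * grid)) ** 2 + ((y - c) / (0.42 * grid)) ** 2 <= 1.0
    stack = np.empty((grid, grid, n_slices))
    for s in range(n_slices):
        img = np.full((grid, grid), 0.08)
        n_blobs = 12
        cx = rng.uniform(0.15 * grid, 0.85 * grid, n_blobs)
        cy = rng.uniform(0.15 * grid, 0.85 * grid, n_blobs)
        sig = rng.uniform(0.04 * grid, 0.14 * grid, n_blobs)
        amp = rng.uniform(0.25, 1.0, n_blobs)
        for j in range(n_blobs):
            img += amp[j] * np.exp(-(((x - cx[j]) ** 2 + (y - cy[j]) ** 2) / (2 * sig[j] ** 2)))
        img *= head  # sharp edge at the head boundary
        img += 0.02  # faint background so intensities stay strictly positive
        stack[:, :, s] = img
    stack /= stack.mean()
    return stack


def make_structural_pair(spec: PhantomSpec) -> tuple[StructuralImage, StructuralImage]:
    """Paired high-res / low-res static structural stacks.

    The low-res stack is the exact ``scale x scale`` block average of
    the high-res one; both share the intensity scale (mean
    ``baseline_mean``).
    """
    rng = np.random.default_rng(spec.seed)
    hi = _tissue_image(spec.grid_hr, spec.n_slices_structural, rng) * spec.baseline_mean
    lo = np.stack(
        [block_average(hi[:, :, s], spec.scale) for s in range(hi.shape[2])], axis=2
    )
    px_lr = 2.0  # mm, EPI-like in-plane pixel; HR pixel is px_lr / scale
    return (
        StructuralImage(hi, pixel_size=px_lr / spec.scale),
        StructuralImage(lo, pixel_size=px_lr),
    )


def _lens_fraction(d: float) -> float:
    """Overlap area of two unit circles at centre distance d, / circle area."""
    if d >= 2.0:
        return 0.0
    if d <= 0.0:
        return 1.0
    area = 2 * np.arccos(d / 2.0) - (d / 2.0) * np.sqrt(4 - d * d)
    return float(area / np.pi)


def _solve_separation(semi_axes: tuple[float, float], frac: float) -> float:
    """Centre distance along x giving |A ∩ B|/|A| = frac for equal ellipses.

    Mapping (x/a, y/b) sends both ellipses to unit circles separated by
    d/a, so the circle lens formula applies exactly.
    """
    a = semi_axes[0]
    if frac <= 0.0:
        return 2.2 * a  # safely disjoint
    return a * float(optimize.brentq(lambda u: _lens_fraction(u) - frac, 1e-9, 2.0 - 1e-9))


def region_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rasterized HR masks for the two active regions.

    Ellipse *shapes* come from the spec geometry; centres are moved
    symmetrically about the midpoint of the two stated centres, along
    the x axis, so the analytic overlap matches ``overlap_fraction``.
    With ``overlap_fraction=None`` (or unequal shapes) the stated
    centres are used as-is.
    """
    ga, gb = spec.region_a_geometry, spec.region_b_geometry
    if spec.overlap_fraction is None or ga.semi_axes != gb.semi_axes:
        mask_a = ga.rasterize(spec.grid_hr)
        mask_b = gb.rasterize(spec.grid_hr)
    else:
        mid_x = 0.5 * (ga.center[0] + gb.center[0])
        mid_y = 0.5 * (ga.center[1] + gb.center[1])
        d = _solve_separation(ga.semi_axes, spec.overlap_fraction)
        mask_a = EllipseGeometry((mid_x - d / 2, mid_y), ga.semi_axes).rasterize(spec.grid_hr)
        mask_b = EllipseGeometry((mid_x + d / 2, mid_y), gb.semi_axes).rasterize(spec.grid_hr)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("region masks are empty; check geometry vs grid")
    return mask_a, mask_b


def separability_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """The default study conditions: two small motor patches (semi-axes
    5 x 3.5 HR px, overlap fraction 0.45) that the low-resolution arm
    cannot resolve but the high-resolution arm partially separates."""
    return PhantomSpec(seed=seed, **overrides)


def recovery_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Geometric-fidelity conditions: larger, well-separated patches
    (semi-axes 12 x 8, centres 44 HR px apart) with moderate structured
    noise, so the native arm's regions should coincide with the
    ground-truth masks."""
    params = dict(
        region_a_geometry=EllipseGeometry((42.0, 64.0), (12.0, 8.0)),
        region_b_geometry=EllipseGeometry((86.0, 64.0), (12.0, 8.0)),
        overlap_fraction=None,
        structured_noise_sd=6.0,
        seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def _structured_noise(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Low-rank physiological-like fluctuations: smooth x slow.

    Sum of ``structured_noise_rank`` separable components, each a
    spatially smooth random field (Gaussian-filtered white noise,
    ``structured_noise_scale`` HR pixels) times a band-limited random
    timecourse (white noise low-passed at ``structured_noise_cutoff``
    Hz).  Unlike i.i.d. noise this component survives both spatial
    smoothing and temporal low-pass filtering, which is what keeps real
    CC maps from being arbitrarily clean.
    """
    from scipy import signal as _signal

    g, t_len, k = spec.grid_hr, spec.n_volumes, spec.structured_noise_rank
    fields = np.empty((g * g, k))
    for i in range(k):
        f = ndimage.gaussian_filter(
            rng.standard_normal((g, g)), spec.structured_noise_scale, mode="reflect"
        )
        fields[:, i] = (f / f.std()).ravel()
    sos = _signal.butter(
        2, spec.structured_noise_cutoff, btype="low", fs=1.0 / spec.tr, output="sos"
    )
    courses = _signal.sosfiltfilt(sos, rng.standard_normal((k, t_len)), axis=1)
    courses /= courses.std(axis=1, keepdims=True)
    noise = (fields @ courses) / np.sqrt(k)
    return spec.structured_noise_sd * noise.reshape(g, g, t_len)


def default_task_design(
    n_volumes: int = 900,
    tr: float = 0.5,
    task_s: float = 20.0,
    rest_s: float = 40.0,
    lead_in_s: float = 30.0,
) -> TaskDesign:
    """Alternating thumb / rest / little-finger / rest block paradigm.

    Defaults: 20 s task blocks separated by 40 s rests (a sparse duty
    cycle keeps the two task references only weakly anti-correlated),
    preceded by a lead-in rest covering the equilibration frames that
    the analysis discards.
    """
    total = n_volumes * tr
    cycle = 2.0 * (task_s + rest_s)
    blocks: list[tuple[str, float, float]] = []
    t = lead_in_s
    while t + cycle <= total:
        blocks.append((TASK_A, t, task_s))
        blocks.append((TASK_B, t + task_s + rest_s, task_s))
        t += cycle
    if not blocks:
        raise ValueError("series too short for the default block design")
    return TaskDesign(blocks=blocks, tr=tr, n_volumes=n_volumes)


def task_responses(spec: PhantomSpec, design: TaskDesign) -> dict[str, np.ndarray]:
    """HRF-convolved boxcar per task, peak-normalised to 1."""
    out = {}
    h = canonical_hrf(design.tr)
    for label in design.labels:
        conv = np.convolve(design.boxcar(label), h)[: design.n_volumes]
        peak = conv.max()
        if peak <= 0:
            raise ValueError(f"task {label!r} never occurs in the design")
        out[label] = conv / peak
    return out


def make_functional_series(
    spec: PhantomSpec, design: TaskDesign | None = None
) -> tuple[FunctionalSeries, GroundTruth]:
    """Simulate the low-res BOLD series and return it with its ground truth.

    Each voxel in region A (resp. B) carries ``baseline * (1 +
    signal_amplitude * response)``; overlap voxels carry both responses
    additively.  Linear drift and i.i.d. Gaussian noise are added on the
    HR grid, then every frame is block-averaged to the LR grid.
    """
    if design is None:
        design = default_task_design(spec.n_volumes, spec.tr)
    if design.n_volumes != spec.n_volumes or abs(design.tr - spec.tr) > 1e-9:
        raise ValueError(
            f"design length {design.n_volumes}x{design.tr}s does not match "
            f"spec {spec.n_volumes}x{spec.tr}s"
        )
    mask_a, mask_b = region_masks(spec)
    responses = task_responses(spec, design)
    resp_a = responses[design.labels[0]]
    resp_b = responses[design.labels[1]] if len(design.labels) > 1 else np.zeros_like(resp_a)

    rng = np.random.default_rng(spec.seed)
    baseline = _tissue_image(spec.grid_hr, 1, rng)[:, :, 0] * spec.baseline_mean

    g = spec.grid_hr
    t_idx = np.arange(spec.n_volumes)
    # (x, y, time) modulation: 1 + amp * (resp_a in A + resp_b in B)
    mod = np.ones((g, g, spec.n_volumes))
    mod += spec.signal_amplitude * (mask_a[:, :, None] * resp_a[None, None, :])
    mod += spec.signal_amplitude * (mask_b[:, :, None] * resp_b[None, None, :])
    clean_hr = baseline[:, :, None] * mod
    clean_hr = clean_hr + spec.drift_slope * t_idx[None, None, :]

    noisy_hr = clean_hr
    if spec.structured_noise_sd > 0:
        noisy_hr = noisy_hr + _structured_noise(spec, rng)
    if spec.noise_sd > 0:
        noisy_hr = noisy_hr + rng.normal(0.0, spec.noise_sd, size=clean_hr.shape)

    lr = block_average(noisy_hr, spec.scale)

    analysis_hr = ndimage.binary_dilation(
        mask_a | mask_b, iterations=spec.analysis_mask_dilation
    )
    gt = GroundTruth(
        mask_a_hr=mask_a,
        mask_b_hr=mask_b,
        analysis_mask_hr=analysis_hr,
        downsample_operator=f"block_average_{spec.scale}x{spec.scale}",
        clean_series_hr=clean_hr[:, :, None, :],
        noisy_series_hr=noisy_hr[:, :, None, :],
        response_a=resp_a,
        response_b=resp_b,
    )
    px_lr = 2.0
    series = FunctionalSeries(
        data=lr[:, :, None, :], tr=spec.tr, pixel_size=px_lr, slice_thickness=4.0
    )
    return series, gt


def hr_series(gt: GroundTruth, spec: PhantomSpec, noisy: bool = True) -> FunctionalSeries:
    """The phantom's high-res series as a :class:`FunctionalSeries`.

    Used to benchmark the pipeline when a perfect super-resolver is
    substituted for the trained generator.
    """
    data = gt.noisy_series_hr if noisy else gt.clean_series_hr
    return FunctionalSeries(data=data, tr=spec.tr, pixel_size=2.0 / spec.scale, slice_thickness=4.0)
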