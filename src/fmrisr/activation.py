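"""Cross-correlation activation mapping and region extraction.

A per-pixel activation score is the normalised dot product (cosine
similarity) between the pixel's timecourse R_y and an HRF-convolved
task reference R_x:

    CC = (R_x . R_y) / (|R_x| |R_y|)

With both vectors mean-centred (the default, and effectively automatic
after detrending) this is the Pearson correlation.  The
activation-related region is the inclusive superlevel set of the CC map
at the range threshold

    threshold = maxCC - (maxCC - minCC) / 4

i.e. the top quarter of the in-mask CC range.  Super-resolved maps have
pixels four times smaller than native maps over the same area, so pixel
counts are divided by the resolution factor before any comparison
across arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hrf import canonical_hrf
from .io import FunctionalSeries, TaskDesign
from .preprocess import PreprocessConfig, discard_initial, detrend_linear, lowpass_temporal, smooth_spatial

__all__ = [
    "ReferenceTimecourse",
    "CCMap",
    "ActivationRegion",
    "build_reference",
    "cc_map",
    "range_threshold",
    "extract_region",
    "normalized_pixel_count",
    "upsample_mask_nearest",
    "run_arm",
]


@dataclass(frozen=True)
class ReferenceTimecourse:
    """Task reference R_x: HRF-convolved boxcar aligned to the retained frames."""

    values: np.ndarray
    task_label: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("reference must be a nonempty 1D vector")
        if not np.any(v != 0):
            raise ValueError("reference timecourse is all-zero")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CCMap:
    """Per-pixel CC values on one slice; NaN outside the analysis mask."""

    values: np.ndarray
    mask: np.ndarray
    task_label: str
    zero_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if vals.shape != mask.shape:
            raise ValueError("CC map and mask shapes differ")
        inside = vals[mask]
        if inside.size and np.nanmax(np.abs(inside)) > 1 + 1e-9:
            raise ValueError("|CC| exceeds 1")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class ActivationRegion:
    """Thresholded activation-related region with its pixel accounting."""

    mask: np.ndarray
    threshold_used: float
    raw_pixel_count: int
    normalized_count: float
    task_label: str


def build_reference(
    design: TaskDesign,
    task_label: str,
    n_discarded: int = 0,
    hrf: str = "canonical",
) -> ReferenceTimecourse:
    """Boxcar for ``task_label`` convolved with the canonical HRF.

    The first ``n_discarded`` samples are dropped so the reference
    aligns with a series whose equilibration frames were excluded.
    ``hrf="impulse"`` replaces the kernel with a unit impulse (the
    reference is then the boxcar itself) — useful for testing.
    """
    box = design.boxcar(task_label)  # raises KeyError on unknown label
    if hrf == "canonical":
        kernel = canonical_hrf(design.tr)
    elif hrf == "impulse":
        kernel = np.array([1.0])
    else:
        raise ValueError(f"unknown hrf kind {hrf!r}")
    ref = np.convolve(box, kernel)[: design.n_volumes]
    if n_discarded >= design.n_volumes:
        raise ValueError("discarding every sample leaves an empty reference")
    ref = ref[n_discarded:]
    if not np.any(ref != 0):
        raise ValueError(
            f"task {task_label!r} has no activity after discarding {n_discarded} frames"
        )
    return ReferenceTimecourse(values=ref, task_label=task_label)


def cc_map(
    series: FunctionalSeries,
    ref: ReferenceTimecourse,
    mask: np.ndarray | None = None,
    slice_index: int = 0,
    center: bool = True,
) -> CCMap:
    """Per-pixel cosine similarity between timecourses and the reference.

    ``center=True`` mean-centres both vectors first (Pearson
    correlation).  Pixels with zero-variance timecourses get CC = 0 and
    are flagged in ``zero_variance``.
    """
    data = series.data[:, :, slice_index, :]
    nx, ny, nt = data.shape
    if ref.values.size != nt:
        raise ValueError(
            f"reference length {ref.values.size} != series length {nt}"
        )
    if mask is None:
        mask = np.ones((nx, ny), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (nx, ny):
        raise ValueError("mask shape does not match the series grid")

    rx = ref.values.astype(float)
    flat = data.reshape(-1, nt).astype(float)
    if center:
        rx = rx - rx.mean()
        flat = flat - flat.mean(axis=1, keepdims=True)
    rx_norm = np.linalg.norm(rx)
    if rx_norm == 0:
        raise ValueError("reference has zero norm after centering")
    ry_norm = np.linalg.norm(flat, axis=1)
    zero_var = ry_norm == 0
    denom = np.where(zero_var, 1.0, ry_norm) * rx_norm
    cc = (flat @ rx) / denom
    cc[zero_var] = 0.0
    cc = np.clip(cc, -1.0, 1.0).reshape(nx, ny)

    values = np.where(mask, cc, np.nan)
    return CCMap(
        values=values,
        mask=mask,
        task_label=ref.task_label,
        zero_variance=zero_var.reshape(nx, ny) & mask,
    )


def range_threshold(max_cc: float, min_cc: float) -> float:
    """Range threshold: max minus a quarter of the max-min range."""
    return max_cc - (max_cc - min_cc) / 4.0


def extract_region(ccmap: CCMap, resolution_factor: float = 1.0) -> ActivationRegion:
    """Inclusive superlevel set of the CC map at the range threshold.

    The threshold is computed from the in-mask max and min; the region
    is every in-mask pixel with CC >= threshold (ties included), so it
    always contains the argmax and, for a constant map, the whole mask.
    """
    inside = ccmap.values[ccmap.mask]
    if inside.size == 0:
        raise ValueError("analysis mask is empty")
    thr = range_threshold(float(np.max(inside)), float(np.min(inside)))
    region = ccmap.mask & (ccmap.values >= thr)
    raw = int(region.sum())
    return ActivationRegion(
        mask=region,
        threshold_used=thr,
        raw_pixel_count=raw,
        normalized_count=normalized_pixel_count(raw, resolution_factor),
        task_label=ccmap.task_label,
    )


def normalized_pixel_count(raw_count: int | float, resolution_factor: float) -> float:
    """Pixel count divided by the resolution factor (4 for a 2x SR grid)."""
    if resolution_factor < 1:
        raise ValueError("resolution_factor must be >= 1")
    return float(raw_count) / float(resolution_factor)


def upsample_mask_nearest(mask: np.ndarray, scale: int) -> np.ndarray:
    """Nearest-neighbour upsampling of a binary mask by an integer factor."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    return np.repeat(np.repeat(mask, scale, axis=0), scale, axis=1)


def run_arm(
    series: FunctionalSeries,
    design: TaskDesign,
    mask: np.ndarray,
    pre_cfg: PreprocessConfig | None = None,
    generator=None,
    center: bool = True,
    slice_index: int = 0,
) -> dict[str, dict]:
    """Run one analysis arm end to end and return per-task results.

    Native arm (``generator=None``): discard -> detrend -> low-pass ->
    smooth -> CC -> extract, on the series' own grid.  Super-resolution
    arm: frames are upscaled through the trained generator right after
    the discard step, the mask is nearest-neighbour upsampled to the HR
    grid, and pixel counts are normalised by scale^2.

    Returns ``{task_label: {"cc_map": CCMap, "region": ActivationRegion}}``.
    """
    if pre_cfg is None:
        pre_cfg = PreprocessConfig()
    work = discard_initial(series, pre_cfg.n_discard)

    factor = 1.0
    if generator is not None:
        from .sr import superresolve_series  # local import: optional heavy dep

        work = superresolve_series(work, generator)
        mask = upsample_mask_nearest(mask, generator.config.scale)
        factor = float(generator.config.scale**2)

    if pre_cfg.detrend:
        work = detrend_linear(work)
    if pre_cfg.lowpass:
        work = lowpass_temporal(work, pre_cfg.lowpass_cutoff)
    if pre_cfg.smoothing and pre_cfg.spatial_sigma > 0:
        work = smooth_spatial(work, pre_cfg.spatial_sigma)

    results: dict[str, dict] = {}
    for label in design.labels:
        ref = build_reference(design, label, n_discarded=pre_cfg.n_discard)
        cmap = cc_map(work, ref, mask=mask, slice_index=slice_index, center=center)
        region = extract_region(cmap, resolution_factor=factor)
        results[label] = {"cc_map": cmap, "region": region}
    return results
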