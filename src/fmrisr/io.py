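"""NIfTI and YAML I/O with geometry/metadata validation.

The in-memory containers used throughout the package live here:
:class:`FunctionalSeries` (4D BOLD series), :class:`StructuralImage`
(static T2*-weighted slice stack) and :class:`TaskDesign` (block
paradigm).  Arrays are indexed ``(x, y, slice[, time])``, 0-based.
NIfTI-1 is the interchange format for all volumes; task designs and
pipeline configuration travel as YAML.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "FunctionalSeries",
    "StructuralImage",
    "TaskDesign",
    "read_series",
    "write_series",
    "read_structural",
    "write_structural",
    "read_design",
    "write_design",
    "read_mask",
    "write_mask",
]


@dataclass(frozen=True)
class FunctionalSeries:
    """A 4D fMRI series with its sampling geometry.

    Parameters
    ----------
    data:
        Intensities, shape ``(x, y, slice, time)``.
    tr:
        Repetition time in seconds (the temporal sampling interval).
    pixel_size:
        In-plane pixel edge length in mm.
    slice_thickness:
        Through-plane voxel extent in mm.
    """

    data: np.ndarray
    tr: float
    pixel_size: float = 1.0
    slice_thickness: float = 4.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 4:
            raise ValueError(f"functional series must be 4D, got {arr.ndim}D")
        if arr.shape[3] < 1:
            raise ValueError("time dimension must have at least one frame")
        if not np.all(np.isfinite(arr)):
            raise ValueError("functional series contains non-finite values")
        if not (self.tr > 0 and self.pixel_size > 0):
            raise ValueError("tr and pixel_size must be positive")
        object.__setattr__(self, "data", arr)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray, **meta) -> "FunctionalSeries":
        """New series sharing this one's metadata, with ``data`` replaced."""
        return replace(self, data=data, **meta)


@dataclass(frozen=True)
class StructuralImage:
    """A static structural slice stack, shape ``(x, y, slice)``."""

    data: np.ndarray
    pixel_size: float = 1.0
    slice_thickness: float = 4.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:  # single slice is accepted and normalised to 3D
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise ValueError(f"structural image must be 2D or 3D, got {arr.ndim}D")
        if arr.size == 0:
            raise ValueError("structural image is empty")
        if not np.all(np.isfinite(arr)):
            raise ValueError("structural image contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "data", arr)

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class TaskDesign:
    """Block paradigm: labelled (onset, duration) intervals on a TR grid.

    ``blocks`` is a sequence of ``(task_label, onset_s, duration_s)``.
    Blocks of the same label must not overlap, and every block must end
    on or before ``n_volumes * tr`` seconds.
    """

    blocks: Sequence[tuple[str, float, float]]
    tr: float
    n_volumes: int

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be >= 1")
        blocks = [(str(l), float(o), float(d)) for (l, o, d) in self.blocks]
        if not blocks:
            raise ValueError("task design has no blocks")
        total = self.n_volumes * self.tr
        per_label: dict[str, list[tuple[float, float]]] = {}
        for label, onset, dur in blocks:
            if dur <= 0 or onset < 0:
                raise ValueError(f"block {label!r}: onset must be >= 0 and duration > 0")
            if onset + dur > total + 1e-9:
                raise ValueError(
                    f"block {label!r} ends at {onset + dur:g}s, beyond the "
                    f"series end ({total:g}s)"
                )
            per_label.setdefault(label, []).append((onset, onset + dur))
        for label, ivals in per_label.items():
            ivals.sort()
            for (s0, e0), (s1, _e1) in zip(ivals, ivals[1:]):
                if s1 < e0 - 1e-9:
                    raise ValueError(f"overlapping blocks for task {label!r}")
        object.__setattr__(self, "blocks", tuple(blocks))

    @property
    def labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for label, _, _ in self.blocks:
            if label not in seen:
                seen.append(label)
        return tuple(seen)

    def boxcar(self, task_label: str) -> np.ndarray:
        """On/off indicator for ``task_label`` sampled at frame midtimes."""
        if task_label not in self.labels:
            raise KeyError(f"unknown task label {task_label!r}")
        t = (np.arange(self.n_volumes) + 0.5) * self.tr
        box = np.zeros(self.n_volumes)
        for label, onset, dur in self.blocks:
            if label == task_label:
                box[(t >= onset) & (t < onset + dur)] = 1.0
        return box


# ---------------------------------------------------------------------------
# NIfTI round-trips


def _affine(pixel_size: float, slice_thickness: float) -> np.ndarray:
    return np.diag([pixel_size, pixel_size, slice_thickness, 1.0])


def write_series(series: FunctionalSeries, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(series.data, _affine(series.pixel_size, series.slice_thickness))
    img.header.set_data_dtype(series.data.dtype)
    img.header.set_zooms(
        (series.pixel_size, series.pixel_size, series.slice_thickness, series.tr)
    )
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, os.fspath(path))


def read_series(path: str | os.PathLike) -> FunctionalSeries:
    img = nib.load(os.fspath(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got {img.ndim}D")
    zooms = img.header.get_zooms()
    data = np.asarray(img.dataobj)
    return FunctionalSeries(
        data=data,
        tr=float(zooms[3]),
        pixel_size=float(zooms[0]),
        slice_thickness=float(zooms[2]),
    )


def write_structural(image: StructuralImage, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(image.data, _affine(image.pixel_size, image.slice_thickness))
    img.header.set_data_dtype(image.data.dtype)
    img.header.set_zooms((image.pixel_size, image.pixel_size, image.slice_thickness))
    img.header.set_xyzt_units("mm")
    nib.save(img, os.fspath(path))


def read_structural(path: str | os.PathLike) -> StructuralImage:
    img = nib.load(os.fspath(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D structural image, got {img.ndim}D")
    zooms = img.header.get_zooms()
    return StructuralImage(
        data=np.asarray(img.dataobj),
        pixel_size=float(zooms[0]),
        slice_thickness=float(zooms[2]),
    )


def write_mask(mask: np.ndarray, pixel_size: float, path: str | os.PathLike) -> None:
    arr = np.asarray(mask).astype(np.uint8)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    img = nib.Nifti1Image(arr, _affine(pixel_size, 1.0))
    nib.save(img, os.fspath(path))


def read_mask(path: str | os.PathLike) -> np.ndarray:
    img = nib.load(os.fspath(path))
    return np.asarray(img.dataobj) > 0


# ---------------------------------------------------------------------------
# Task-design YAML


def write_design(design: TaskDesign, path: str | os.PathLike) -> None:
    doc = {
        "tr": float(design.tr),
        "n_volumes": int(design.n_volumes),
        "blocks": [
            {"task": label, "onset": onset, "duration": dur}
            for (label, onset, dur) in design.blocks
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_design(path: str | os.PathLike) -> TaskDesign:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: task design must be a YAML mapping")
    for key in ("tr", "n_volumes", "blocks"):
        if key not in doc:
            raise ValueError(f"{path}: missing required key {key!r}")
    blocks = [
        (str(b["task"]), float(b["onset"]), float(b["duration"]))
        for b in doc["blocks"]
    ]
    return TaskDesign(blocks=blocks, tr=float(doc["tr"]), n_volumes=int(doc["n_volumes"]))
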