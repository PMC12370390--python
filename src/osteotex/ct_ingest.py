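"""Reading CT image data and summarizing Hounsfield units in a region of interest.

The pipeline works on stacks of 2-D CT cross-sections expressed in Hounsfield
units (HU).  A bone specimen is scanned along its long axis; texture analysis
is performed on a small number of cross-sections sampled at fixed fractional
positions along that axis (by default 10 sections from 5% to 95% of the
length).  Within each section the region of interest (ROI) is defined purely
by an HU window — all pixels whose CT number falls in the closed interval
[hu_min, hu_max] — which selects bone tissue and excludes marrow and soft
tissue on one side and artefacts above the window on the other.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyROIError, InputError

#: Default HU window selecting bone tissue (trabecular through cortical).
DEFAULT_HU_WINDOW = (250.0, 1000.0)

#: Default cross-section sampling: 10 sections from 5% to 95% of the length.
DEFAULT_N_SLICES = 10
DEFAULT_FRACTION_RANGE = (0.05, 0.95)


@dataclass
class HUVolume:
    """A 3-D stack of CT numbers with physical spacings.

    Parameters
    ----------
    voxels
        Array of shape ``(n_slices, height, width)`` of CT numbers in HU.
    slice_spacing
        Distance between consecutive slices along the bone axis, in mm.
    pixel_spacing
        In-plane pixel size, in mm.
    """

    voxels: np.ndarray
    slice_spacing: float = 1.0
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise InputError("voxels must be a 3-D array with at least one slice")
        if not (self.slice_spacing > 0 and self.pixel_spacing > 0):
            raise InputError("spacings must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise InputError("HU values must be finite")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def axis_length(self) -> float:
        """Physical extent along the stack axis, in mm."""
        return self.n_slices * self.slice_spacing


@dataclass
class HUSlice:
    """A single 2-D cross-section with an optional ROI mask.

    ``mask`` marks the pixels that belong to the region of interest; it
    defaults to all-true.  ``position_fraction`` records where along the bone
    axis the section was taken (0 = proximal end of the stack, 1 = distal).
    """

    pixels: np.ndarray
    mask: np.ndarray | None = None
    position_fraction: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InputError("slice pixels must be 2-D")
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise InputError("mask shape must equal pixel shape")

    @property
    def masked_values(self) -> np.ndarray:
        return self.pixels[self.mask]


@dataclass(frozen=True)
class ROIStats:
    """Mean and spread of CT numbers over the ROI of one slice."""

    mean_hu: float
    sd_hu: float
    n_pixels: int


def load_hu_volume(
    path: str | os.PathLike,
    fmt: str | None = None,
    rescale_slope: float | None = None,
    rescale_intercept: float | None = None,
    slice_spacing: float | None = None,
    pixel_spacing: float | None = None,
) -> HUVolume:
    """Read a CT volume from a DICOM series or a TIFF stack, in HU.

    Raw stored values are converted to Hounsfield units with the affine map
    ``HU = raw * slope + intercept``.  For DICOM input the slope/intercept
    default to the per-file header values (RescaleSlope/RescaleIntercept);
    for TIFF they default to the identity (slope 1, intercept 0) and should
    be passed explicitly when the stack stores offset integer values.

    Parameters
    ----------
    path
        A multi-page TIFF file, or a directory containing one DICOM file per
        slice.
    fmt
        ``"dicom-series"`` or ``"tiff-stack"``; inferred from ``path`` when
        omitted (directory → DICOM, file → TIFF).
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"input path does not exist: {p}")
    if fmt is None:
        fmt = "dicom-series" if p.is_dir() else "tiff-stack"

    if fmt == "tiff-stack":
        import tifffile

        try:
            raw = tifffile.imread(str(p))
        except Exception as exc:  # pragma: no cover - corrupt-file path
            raise InputError(f"could not read TIFF stack {p}: {exc}") from exc
        raw = np.asarray(raw, dtype=float)
        if raw.ndim == 2:
            raw = raw[None, :, :]
        if raw.ndim != 3:
            raise InputError(f"TIFF stack must be 2-D or 3-D, got shape {raw.shape}")
        slope = 1.0 if rescale_slope is None else rescale_slope
        intercept = 0.0 if rescale_intercept is None else rescale_intercept
        hu = raw * slope + intercept
        return HUVolume(
            hu,
            slice_spacing=slice_spacing or 1.0,
            pixel_spacing=pixel_spacing or 1.0,
        )

    if fmt == "dicom-series":
        return _load_dicom_series(
            p, rescale_slope, rescale_intercept, slice_spacing, pixel_spacing
        )

    raise InputError(f"unknown format {fmt!r}")


def _load_dicom_series(
    p: Path,
    rescale_slope: float | None,
    rescale_intercept: float | None,
    slice_spacing: float | None,
    pixel_spacing: float | None,
) -> HUVolume:
    import pydicom

    files = sorted(p.glob("*.dcm")) if p.is_dir() else [p]
    if not files:
        files = sorted(f for f in p.iterdir() if f.is_file()) if p.is_dir() else []
    if not files:
        raise InputError(f"no DICOM files found under {p}")

    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception as exc:
            raise InputError(f"could not read DICOM file {f}: {exc}") from exc

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None and len(pos) == 3:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)

    slices = []
    for ds in datasets:
        raw = ds.pixel_array.astype(float)
        slope = (
            rescale_slope
            if rescale_slope is not None
            else float(getattr(ds, "RescaleSlope", 1.0))
        )
        intercept = (
            rescale_intercept
            if rescale_intercept is not None
            else float(getattr(ds, "RescaleIntercept", 0.0))
        )
        slices.append(raw * slope + intercept)

    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise InputError(f"inconsistent slice shapes in series: {sorted(shapes)}")

    ds0 = datasets[0]
    if slice_spacing is None:
        slice_spacing = float(getattr(ds0, "SliceThickness", 1.0) or 1.0)
    if pixel_spacing is None:
        ps = getattr(ds0, "PixelSpacing", None)
        pixel_spacing = float(ps[0]) if ps else 1.0
    return HUVolume(
        np.stack(slices), slice_spacing=slice_spacing, pixel_spacing=pixel_spacing
    )


def select_cross_sections(
    volume: HUVolume,
    n_slices: int = DEFAULT_N_SLICES,
    lo_frac: float = DEFAULT_FRACTION_RANGE[0],
    hi_frac: float = DEFAULT_FRACTION_RANGE[1],
) -> list[HUSlice]:
    """Sample cross-sections at equally spaced fractional positions.

    The requested positions are ``n_slices`` fractions linearly spaced from
    ``lo_frac`` to ``hi_frac`` inclusive.  A fraction maps to a stack index by
    ``round(frac * (N - 1))`` with ties rounding half up, where ``N`` is the
    number of slices in the volume.
    """
    if not (0.0 <= lo_frac < hi_frac <= 1.0):
        raise InputError("require 0 <= lo_frac < hi_frac <= 1")
    if n_slices < 1:
        raise InputError("n_slices must be >= 1")
    total = volume.n_slices
    if n_slices > total:
        raise InputError(
            f"requested {n_slices} cross-sections from a {total}-slice volume"
        )
    fractions = np.linspace(lo_frac, hi_frac, n_slices)
    out = []
    for frac in fractions:
        idx = int(math.floor(frac * (total - 1) + 0.5))  # round half up
        out.append(HUSlice(volume.voxels[idx], position_fraction=float(frac)))
    return out


def extract_roi(
    slc: HUSlice,
    hu_min: float = DEFAULT_HU_WINDOW[0],
    hu_max: float = DEFAULT_HU_WINDOW[1],
) -> HUSlice:
    """Build the ROI mask from an HU window (closed interval).

    The mask is true exactly where ``hu_min <= pixel <= hu_max``; the pixel
    values are left untouched.  An all-false mask is legal here — downstream
    texture/statistics calls raise :class:`EmptyROIError` when they need at
    least one pixel.
    """
    if not hu_min < hu_max:
        raise InputError("require hu_min < hu_max")
    mask = (slc.pixels >= hu_min) & (slc.pixels <= hu_max)
    return HUSlice(slc.pixels, mask=mask, position_fraction=slc.position_fraction)


def roi_hu_stats(slc: HUSlice) -> ROIStats:
    """Mean and sample SD of CT numbers over the masked pixels.

    The SD uses the n−1 denominator; a single-pixel ROI reports SD 0.
    """
    values = slc.masked_values
    if values.size == 0:
        raise EmptyROIError("no bone tissue in ROI (empty mask)")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return ROIStats(mean_hu=float(np.mean(values)), sd_hu=sd, n_pixels=int(values.size))


def roi_stats_table(
    slices: Iterable[HUSlice], specimen_id: str = "specimen"
) -> "list[dict]":
    """Per-slice ROI statistics rows (specimen_id, slice_fraction, n, mean, SD)."""
    rows = []
    for slc in slices:
        stats = roi_hu_stats(slc)
        rows.append(
            {
                "specimen_id": specimen_id,
                "slice_fraction": slc.position_fraction,
                "n_pixels": stats.n_pixels,
                "mean_hu": stats.mean_hu,
                "sd_hu": stats.sd_hu,
            }
        )
    return rows
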