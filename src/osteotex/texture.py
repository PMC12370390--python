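"""Grey-level co-occurrence matrices and second-order texture features.

A grey-level co-occurrence matrix (GLCM) counts how often pairs of quantized
grey tones occur at a fixed pixel displacement, and normalizes the counts to
a joint probability P(i, j).  Five scalar statistics of that distribution —
energy, entropy, contrast, homogeneity, and correlation — summarize the
spatial texture of trabecular bone in a CT cross-section, and together with
the ROI mean HU they form the six-element input of the modulus regression
network.

The implementation is mask-aware: a pixel pair contributes to the matrix only
if *both* pixels lie inside the ROI mask, so irregular bone regions can be
analysed without the background leaking into the statistics.  Orientation
convention (image coordinates, row down / column right):

====  ===========
  0°  (0, +1)
 45°  (−1, +1)
 90°  (−1, 0)
====  ===========

all at displacement one; matrices for the orientations are averaged before
the features are evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ct_ingest import DEFAULT_HU_WINDOW, HUSlice, roi_hu_stats
from .errors import EmptyROIError, InputError

#: Row/column displacements for 0°, 45°, 90° at unit displacement.
ORIENTATION_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0)}
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = tuple(ORIENTATION_OFFSETS.values())

#: Default grey-tone count for quantization.
DEFAULT_NG = 8

_NORMALIZATION_TOL = 1e-9


@dataclass
class QuantizedImage:
    """Integer grey tones in [0, ng−1] with the ROI mask carried along."""

    levels: np.ndarray
    mask: np.ndarray
    ng: int

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.ng < 2:
            raise InputError("ng must be >= 2")
        if self.levels.shape != self.mask.shape:
            raise InputError("levels and mask shapes differ")
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 0 or inside.max() >= self.ng):
            raise InputError("masked grey tones must lie in [0, ng-1]")


@dataclass
class GLCM:
    """Normalized co-occurrence probabilities P(i, j) over ng grey tones."""

    p: np.ndarray
    ng: int
    offsets: tuple[tuple[int, int], ...]
    n_pairs: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.ng, self.ng):
            raise InputError("GLCM must be ng x ng")
        if np.any(self.p < 0):
            raise InputError("GLCM entries must be non-negative")
        if self.n_pairs > 0 and abs(self.p.sum() - 1.0) > _NORMALIZATION_TOL:
            raise InputError("GLCM probabilities must sum to 1")


@dataclass(frozen=True)
class TextureFeatures:
    """The five co-occurrence statistics plus the marginal moments.

    ``correlation_defined`` is false when either marginal SD is zero (a
    constant ROI); correlation is then reported as 0 rather than raising, so
    a degenerate slice does not abort a batch run.
    """

    energy: float
    entropy: float
    contrast: float
    homogeneity: float
    correlation: float
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    correlation_defined: bool = True


@dataclass(frozen=True)
class FeatureVector:
    """The six network inputs: five texture features and the ROI mean HU."""

    energy: float
    entropy: float
    contrast: float
    homogeneity: float
    correlation: float
    mean_hu: float

    FIELDS = ("energy", "entropy", "contrast", "homogeneity", "correlation", "mean_hu")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS], dtype=float)


def quantize(
    slc: HUSlice,
    ng: int = DEFAULT_NG,
    range_policy: str = "fixed-window",
    window: tuple[float, float] = DEFAULT_HU_WINDOW,
) -> QuantizedImage:
    """Linearly bin masked HU values into ``ng`` equal-width grey tones.

    ``range_policy="fixed-window"`` bins over the fixed HU window (so grey
    tones are comparable across slices and specimens); ``"roi-minmax"`` bins
    over the min/max of the masked pixels of this slice.  Bins are half-open
    with the top edge inclusive; a constant region maps entirely to level 0.
    """
    if ng < 2:
        raise InputError("ng must be >= 2")
    values = slc.masked_values
    if values.size == 0:
        raise EmptyROIError("cannot quantize an empty ROI")
    if range_policy == "fixed-window":
        lo, hi = float(window[0]), float(window[1])
        if not lo < hi:
            raise InputError("window must be ordered")
    elif range_policy == "roi-minmax":
        lo, hi = float(values.min()), float(values.max())
    else:
        raise InputError(f"unknown range_policy {range_policy!r}")

    if hi == lo:  # constant ROI under roi-minmax
        levels = np.zeros(slc.pixels.shape, dtype=np.intp)
    else:
        scaled = (slc.pixels - lo) / (hi - lo) * ng
        levels = np.clip(np.floor(scaled), 0, ng - 1).astype(np.intp)
    return QuantizedImage(levels=levels, mask=slc.mask.copy(), ng=ng)


def compute_glcm(
    qimg: QuantizedImage, offset: tuple[int, int], symmetric: bool = True
) -> GLCM:
    """Count grey-tone pairs at one displacement and normalize.

    A pair (reference pixel, neighbour at ``offset``) contributes only when
    both pixels are inside the mask.  With ``symmetric=True`` each pair is
    also counted in the reverse order (the matrix equals its transpose), so
    the row and column marginals coincide.
    """
    dr, dc = int(offset[0]), int(offset[1])
    if (dr, dc) == (0, 0):
        raise InputError("offset must be non-zero")
    lv, mask, ng = qimg.levels, qimg.mask, qimg.ng
    h, w = lv.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    counts = np.zeros((ng, ng), dtype=float)
    if r1 > r0 and c1 > c0:
        src = lv[r0:r1, c0:c1]
        tgt = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if valid.any():
            flat = src[valid].astype(np.intp) * ng + tgt[valid].astype(np.intp)
            counts = (
                np.bincount(flat, minlength=ng * ng).reshape(ng, ng).astype(float)
            )
    if symmetric:
        counts = counts + counts.T
    n_pairs = int(counts.sum())
    if n_pairs == 0:
        raise EmptyROIError(
            f"no valid pixel pairs in ROI at offset ({dr}, {dc}); "
            "region too small or fragmented for texture analysis"
        )
    return GLCM(p=counts / counts.sum(), ng=ng, offsets=((dr, dc),), n_pairs=n_pairs)


def average_glcm(glcms: Sequence[GLCM]) -> GLCM:
    """Element-wise mean of co-occurrence matrices (still sums to 1)."""
    if len(glcms) == 0:
        raise InputError("cannot average an empty list of GLCMs")
    ng = glcms[0].ng
    if any(g.ng != ng for g in glcms):
        raise InputError("all GLCMs must share the same ng")
    p = np.mean([g.p for g in glcms], axis=0)
    offsets = tuple(o for g in glcms for o in g.offsets)
    return GLCM(p=p, ng=ng, offsets=offsets, n_pairs=sum(g.n_pairs for g in glcms))


def haralick_features(glcm: GLCM, log_base: float | str = 2) -> TextureFeatures:
    """Energy, entropy, contrast, homogeneity, correlation of one GLCM.

    With P = P(i, j) over grey tones i, j = 0 … ng−1:

    * energy       = ΣΣ P²
    * entropy      = −ΣΣ P log P            (0·log 0 := 0)
    * contrast     = ΣΣ (i−j)² P
    * homogeneity  = ΣΣ P / (1 + (i−j)²)
    * correlation  = (ΣΣ i·j·P − μx·μy) / (σx·σy)

    where μ and σ are the means/SDs of the row and column marginal
    distributions.  ``log_base`` is 2 (entropy in bits) or "e" (nats).
    """
    p = glcm.p
    if abs(p.sum() - 1.0) > _NORMALIZATION_TOL:
        raise InputError("haralick_features requires a normalized GLCM")
    ng = glcm.ng
    i = np.arange(ng, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    energy = float(np.sum(p * p))
    nz = p > 0
    if log_base in (2, "2"):
        logs = np.log2(p[nz])
    elif log_base in ("e", math.e):
        logs = np.log(p[nz])
    else:
        logs = np.log(p[nz]) / math.log(float(log_base))
    entropy = float(-np.sum(p[nz] * logs))
    diff2 = (ii - jj) ** 2
    contrast = float(np.sum(diff2 * p))
    homogeneity = float(np.sum(p / (1.0 + diff2)))

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sigma_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sigma_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))

    if sigma_x * sigma_y > 0:
        correlation = float((np.sum(ii * jj * p) - mu_x * mu_y) / (sigma_x * sigma_y))
        defined = True
    else:
        correlation, defined = 0.0, False

    return TextureFeatures(
        energy=energy,
        entropy=max(entropy, 0.0),
        contrast=contrast,
        homogeneity=homogeneity,
        correlation=correlation,
        mu_x=mu_x,
        mu_y=mu_y,
        sigma_x=sigma_x,
        sigma_y=sigma_y,
        correlation_defined=defined,
    )


def feature_vector(
    slc: HUSlice,
    ng: int = DEFAULT_NG,
    offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS,
    symmetric: bool = True,
    log_base: float | str = 2,
    range_policy: str = "fixed-window",
    window: tuple[float, float] = DEFAULT_HU_WINDOW,
) -> FeatureVector:
    """Quantize → per-offset GLCMs → average → features, plus ROI mean HU.

    This is the full per-slice feature extraction: the five texture
    statistics are evaluated on the matrix averaged over the configured
    orientations, and the sixth input is the mean CT number over the ROI.
    Deterministic for fixed inputs.
    """
    qimg = quantize(slc, ng=ng, range_policy=range_policy, window=window)
    glcms = [compute_glcm(qimg, off, symmetric=symmetric) for off in offsets]
    feats = haralick_features(average_glcm(glcms), log_base=log_base)
    stats = roi_hu_stats(slc)
    return FeatureVector(
        energy=feats.energy,
        entropy=feats.entropy,
        contrast=feats.contrast,
        homogeneity=feats.homogeneity,
        correlation=feats.correlation,
        mean_hu=stats.mean_hu,
    )


def summarize_features(table) -> "pandas.DataFrame":
    """Descriptive statistics (mean ± SD, mode, median, range) per feature.

    ``table`` is a DataFrame with one row per analysed slice and the six
    feature columns; the summary mirrors the mean/SD/mode/median/range
    report format used for study-population image characteristics.
    """
    import pandas as pd

    rows = []
    for col in FeatureVector.FIELDS:
        if col not in table.columns:
            continue
        v = table[col].astype(float)
        mode = v.round(2).mode()
        rows.append(
            {
                "feature": col,
                "mean": v.mean(),
                "sd": v.std(ddof=1),
                "mode": float(mode.iloc[0]) if len(mode) else float("nan"),
                "median": v.median(),
                "range": v.max() - v.min(),
            }
        )
    return pd.DataFrame(rows).set_index("feature")
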