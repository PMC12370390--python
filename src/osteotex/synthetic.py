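"""Synthetic trabecular phantoms, specimen cohorts, and bending curves.

Every pipeline stage can be exercised without scan data.  The slice phantom
is the standard thresholded-Gaussian-random-field construction of trabecular
structure: a seeded white-noise image is smoothed with a Gaussian kernel
whose width sets the structure scale (trabecular thickness, in pixels), and
thresholded at the quantile that realizes a target bone-area fraction — the
2-D analogue of BV/TV.  Bone-phase pixels receive CT numbers that increase
with the field's height above the threshold (a partial-volume /
mineralization proxy), so both the mean HU and the co-occurrence texture of
a phantom carry the area-fraction signal; marrow-phase pixels fall below
the bone HU window.  Additive HU noise is Gaussian, clipped at ±4σ so the
phases stay inside their configured HU ranges.

A cohort couples each phantom to a ground-truth Young's modulus through an
apparent density that is affine in the bone-area fraction and a configurable
density–modulus power law, giving feature→modulus datasets with known
generating structure for training and validating the regression network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .ct_ingest import DEFAULT_HU_WINDOW, HUSlice, extract_roi
from .errors import InputError
from .mechanics import PowerLawModel, RABBIT_LAW, SpecimenRecord, eval_power_law
from .texture import DEFAULT_NG, DEFAULT_OFFSETS, FeatureVector, feature_vector

#: Default phantom HU ranges: marrow stays below the 250-HU window edge and
#: bone stays inside [250, 1000] even after ±4σ clipped noise, so the HU
#: window recovers exactly the generated bone phase.
DEFAULT_HU_BONE_RANGE = (300.0, 950.0)
DEFAULT_HU_MARROW_RANGE = (-80.0, 200.0)
DEFAULT_NOISE_SD = 10.0


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for one trabecular slice phantom.

    ``correlation_length`` is the Gaussian smoothing sigma in pixels and
    controls trabecular structure scale; ``bone_area_fraction`` is the
    target 2-D BV/TV.
    """

    bone_area_fraction: float = 0.5
    correlation_length: float = 3.0
    hu_bone_range: tuple[float, float] = DEFAULT_HU_BONE_RANGE
    hu_marrow_range: tuple[float, float] = DEFAULT_HU_MARROW_RANGE
    noise_sd: float = DEFAULT_NOISE_SD
    image_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.bone_area_fraction < 1.0:
            raise InputError("bone_area_fraction must be in (0, 1)")
        if self.image_size < 16:
            raise InputError("image_size must be >= 16")
        if not (self.hu_bone_range[0] < self.hu_bone_range[1]):
            raise InputError("hu_bone_range must be ordered")
        if not (self.hu_marrow_range[0] < self.hu_marrow_range[1]):
            raise InputError("hu_marrow_range must be ordered")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        if self.correlation_length <= 0:
            raise InputError("correlation_length must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually produced for one phantom."""

    true_bone_area_fraction: float
    true_modulus: float | None = None
    generating_law: str | None = None


def make_trabecular_slice(params: PhantomParams) -> tuple[HUSlice, GroundTruth]:
    """Render one phantom cross-section with known bone-area fraction.

    Deterministic per seed.  The quantile threshold realizes the target
    fraction up to pixel-count discreteness (well within ±0.02 for sizes
    ≥ 128²); the returned ground truth records the realized fraction.
    """
    rng = np.random.default_rng(params.seed)
    n = params.image_size
    g = gaussian_filter(rng.standard_normal((n, n)), params.correlation_length)
    t = float(np.quantile(g, 1.0 - params.bone_area_fraction))
    bone = g >= t
    if not bone.any() or bone.all():
        raise InputError(
            f"bone_area_fraction {params.bone_area_fraction} produced a "
            "single-phase image; fraction too extreme for this size"
        )

    hu = np.empty((n, n), dtype=float)
    mlo, mhi = params.hu_marrow_range
    blo, bhi = params.hu_bone_range
    # marrow: uniform over its range
    hu[~bone] = rng.uniform(mlo, mhi, size=int((~bone).sum()))
    # bone: HU grows with the field's height above threshold (partial-volume
    # / mineralization proxy).  Height is normalized by the field SD, not the
    # per-slice max, so a larger bone fraction (lower threshold) shifts the
    # whole bone-HU distribution upward and mean HU tracks the area fraction.
    height = g[bone] - t
    sigma_g = float(g.std())
    rel = height / (2.5 * sigma_g) if sigma_g > 0 else np.zeros_like(height)
    jitter = rng.uniform(-0.05, 0.05, size=rel.size)
    hu[bone] = blo + np.clip(rel + jitter, 0.0, 1.0) * (bhi - blo)
    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, size=(n, n))
        np.clip(noise, -4 * params.noise_sd, 4 * params.noise_sd, out=noise)
        hu += noise
        # keep each phase inside its configured range after noise
        hu[bone] = np.clip(hu[bone], blo - 4 * params.noise_sd, bhi + 4 * params.noise_sd)
        hu[~bone] = np.clip(hu[~bone], mlo - 4 * params.noise_sd, mhi + 4 * params.noise_sd)

    truth = GroundTruth(true_bone_area_fraction=float(bone.mean()))
    return HUSlice(pixels=hu), truth


#: Affine map from bone-area fraction to apparent ash density
#: (×10⁻³ kg/m³): fraction 0.2 → 0.58, fraction 0.8 → 2.02, spanning the
#: tabulated rabbit calibration range 0.42–1.97.
DEFAULT_DENSITY_INTERCEPT = 0.1
DEFAULT_DENSITY_SLOPE = 2.4


def fraction_to_density(
    fraction,
    intercept: float = DEFAULT_DENSITY_INTERCEPT,
    slope: float = DEFAULT_DENSITY_SLOPE,
):
    """Apparent density as an affine function of bone-area fraction."""
    return intercept + slope * np.asarray(fraction, dtype=float)


def make_specimen_cohort(
    n: int,
    law: PowerLawModel = RABBIT_LAW,
    fraction_range: tuple[float, float] = (0.2, 0.8),
    noise_sd_e: float = 0.05,
    seed: int = 0,
    image_size: int = 128,
    correlation_length: float = 3.0,
    density_intercept: float = DEFAULT_DENSITY_INTERCEPT,
    density_slope: float = DEFAULT_DENSITY_SLOPE,
    ng: int = DEFAULT_NG,
    offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS,
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW,
) -> "pandas.DataFrame":
    """Generate a paired (features, modulus) dataset of n phantom slices.

    Per sample: draw a bone-area fraction uniformly from ``fraction_range``,
    render a phantom, apply the HU-window ROI, compute the six-element
    feature vector, and set the target modulus E = law(density)·(1 + ε)
    with density affine in the fraction and ε ~ N(0, noise_sd_e) truncated
    at ±4σ (``noise_sd_e`` is relative noise).  All per-slice randomness
    derives from the single cohort seed through a counter, so any slice can
    be regenerated independently.

    Returns a DataFrame with the six feature columns plus ``fraction``,
    ``density``, and ``e_true``.
    """
    import pandas as pd

    if n < 10:
        raise InputError("cohort size must be >= 10")
    lo, hi = fraction_range
    if not (0 < lo <= hi < 1):
        raise InputError("fraction_range must lie inside (0, 1)")
    rng = np.random.default_rng(seed)
    fractions = rng.uniform(lo, hi, size=n)
    eps = rng.normal(0.0, 1.0, size=n)
    np.clip(eps, -4.0, 4.0, out=eps)

    rows = []
    for i in range(n):
        slice_seed = int((seed * 1_000_003 + i) % (2**31 - 1))
        params = PhantomParams(
            bone_area_fraction=float(fractions[i]),
            correlation_length=correlation_length,
            image_size=image_size,
            seed=slice_seed,
        )
        slc, truth = make_trabecular_slice(params)
        roi = extract_roi(slc, *hu_window)
        fv = feature_vector(roi, ng=ng, offsets=offsets, window=hu_window)
        density = float(
            fraction_to_density(
                truth.true_bone_area_fraction, density_intercept, density_slope
            )
        )
        e_true = eval_power_law(law, density) * (1.0 + noise_sd_e * eps[i])
        rows.append(
            {
                **{f: getattr(fv, f) for f in FeatureVector.FIELDS},
                "fraction": truth.true_bone_area_fraction,
                "density": density,
                "e_true": float(e_true),
                "slice_seed": slice_seed,
            }
        )
    return pd.DataFrame(rows)


def simulate_bending_curve(
    e_true: float,
    span: float,
    second_moment: float,
    max_load: float,
    n_points: int = 200,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic elastic three-point-bending load–displacement samples.

    displacement = load·span³ / (48·E·I) + Gaussian noise (mm).  The linear
    slope — hence the modulus — is recoverable by least squares.
    Returns (loads [N], displacements [mm]).
    """
    if e_true <= 0 or span <= 0 or second_moment <= 0:
        raise InputError("modulus, span and second moment must be positive")
    if max_load <= 0:
        raise InputError("max_load must be positive (empty curve)")
    if n_points < 2:
        raise InputError("need at least 2 sample points")
    loads = np.linspace(0.0, max_load, n_points)
    disp = loads * span**3 / (48.0 * e_true * second_moment)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        disp = disp + rng.normal(0.0, noise_sd, size=n_points)
    return loads, disp


def table4_fixture(as_records: bool = False):
    """The packaged 15-specimen rabbit calibration table.

    Columns: specimen_id, ash_density (×10⁻³ kg/m³), e_measured (MPa),
    e_powerlaw (MPa, as tabulated), residual (squared difference, as
    tabulated).  With ``as_records=True`` the rows are returned as
    :class:`~osteotex.mechanics.SpecimenRecord` objects carrying
    ash_density and measured modulus.
    """
    import pandas as pd

    with resources.files("osteotex.data").joinpath("table4.csv").open() as f:
        df = pd.read_csv(f)
    if not as_records:
        return df
    return [
        SpecimenRecord(
            specimen_id=str(int(r.specimen_id)),
            ash_density=float(r.ash_density),
            modulus=float(r.e_measured),
        )
        for r in df.itertuples()
    ]


def write_phantom(slc: HUSlice, truth: GroundTruth, path_stem) -> None:
    """Write a phantom slice as 16-bit TIFF plus a JSON ground-truth sidecar."""
    import json
    from pathlib import Path

    import tifffile

    stem = Path(path_stem)
    tifffile.imwrite(str(stem.with_suffix(".tif")), np.round(slc.pixels).astype(np.int16))
    stem.with_suffix(".json").write_text(
        json.dumps(
            {
                "true_bone_area_fraction": truth.true_bone_area_fraction,
                "true_modulus": truth.true_modulus,
                "generating_law": truth.generating_law,
            },
            indent=2,
        )
    )
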