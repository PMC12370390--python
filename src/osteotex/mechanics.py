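"""Mechanical-test reduction and the density–modulus power-law calibration.

Three-point bending of a bone specimen gives the flexural Young's modulus

    E = (F/Δ) · L³ / (48 · I)

from the slope F/Δ of the load–displacement line, the support span L, and
the second moment of area I of the narrowest cross-section.  An ash test
gives a specimen density from dry weight w1, ash weight w2 and volume v1;
the calibration then connects density ρ and modulus E through the power law
E = a·ρ^b.

The reference rabbit-femur calibration is E = 2.098247·ρ^0.126871 (ρ in
×10⁻³ kg/m³ as tabulated, E in MPa); the human cortical-bone law from the
literature, E = 3.891·ρ^2.39, is carried alongside as a second target law.
Units are used exactly as tabulated — the calibration is scale-consistent
as long as inputs follow the same convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import FitError, InputError


@dataclass
class SpecimenRecord:
    """One physical specimen: ash-test and bending-test measurements.

    Derived quantities (``ash_density``, ``modulus``) may be supplied
    directly — e.g. for tabulated calibration data — or computed from the
    raw measurements with :meth:`reduce`.
    """

    specimen_id: str
    w1: float | None = None  # dry weight, g
    w2: float | None = None  # ash weight, g
    v1: float | None = None  # volume, mm^3
    slope: float | None = None  # load-displacement slope, N/mm
    span: float | None = None  # support span, mm
    second_moment: float | None = None  # second moment of area, mm^4
    ash_density: float | None = None  # x 1e-3 kg/m^3, as tabulated
    modulus: float | None = None  # MPa

    def reduce(self, density_convention: str = "dry-minus-ash") -> "SpecimenRecord":
        """Fill in ash_density and modulus from the raw measurements."""
        if self.ash_density is None:
            if None in (self.w1, self.w2, self.v1):
                raise InputError(f"{self.specimen_id}: missing ash-test data")
            self.ash_density = ash_density(
                self.w1, self.w2, self.v1, convention=density_convention
            )
        if self.modulus is None:
            if None in (self.slope, self.span, self.second_moment):
                raise InputError(f"{self.specimen_id}: missing bending-test data")
            self.modulus = flexural_modulus(self.slope, self.span, self.second_moment)
        return self


@dataclass(frozen=True)
class PowerLawModel:
    """E = coefficient · ρ^exponent, with optional fit diagnostics."""

    coefficient: float  # MPa
    exponent: float
    standard_error: float | None = None
    fit_method: str = "reported"

    def __post_init__(self) -> None:
        if not self.coefficient > 0:
            raise InputError("power-law coefficient must be positive")


#: Rabbit-femur calibration (15-specimen bending + ash data).
RABBIT_LAW = PowerLawModel(2.098247, 0.126871, standard_error=0.1383)

#: Human cortical-bone density-modulus law from the literature.
HUMAN_LAW = PowerLawModel(3.891, 2.39)


def ash_density(
    w1: float, w2: float, v1: float, convention: str = "dry-minus-ash"
) -> float:
    """Specimen density from the ash test.

    ``convention="dry-minus-ash"`` returns (w1 − w2)/v1, the form used for
    the reference calibration; ``"ash-weight"`` returns the conventional
    mineral density w2/v1.
    """
    if v1 <= 0:
        raise InputError("volume must be positive")
    if w2 > w1:
        raise InputError("ash weight cannot exceed dry weight")
    if w2 < 0:
        raise InputError("weights must be non-negative")
    if convention == "dry-minus-ash":
        return (w1 - w2) / v1
    if convention == "ash-weight":
        return w2 / v1
    raise InputError(f"unknown ash-density convention {convention!r}")


def flexural_modulus(slope: float, span: float, second_moment: float) -> float:
    """Flexural Young's modulus from three-point bending.

    E = slope · span³ / (48 · I); MPa when inputs are N/mm, mm, mm⁴.
    """
    if slope <= 0 or span <= 0 or second_moment <= 0:
        raise InputError("slope, span and second moment must all be positive")
    return slope * span**3 / (48.0 * second_moment)


def _loglog_ols(rho: np.ndarray, e: np.ndarray) -> tuple[float, float]:
    """Closed-form simple linear regression on (ln ρ, ln E)."""
    x, y = np.log(rho), np.log(e)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    b = float(np.sum((x - xm) * (y - ym)) / sxx) if sxx > 0 else 0.0
    a = math.exp(ym - b * xm)
    return a, b


def fit_power_law(
    rho: Sequence[float],
    e: Sequence[float],
    method: str = "nonlinear-ls",
) -> PowerLawModel:
    """Fit E = a·ρ^b to (density, modulus) pairs.

    ``method="log-log-ols"`` is ordinary least squares on the logarithms
    (closed form); ``"nonlinear-ls"`` minimizes squared error on the
    original scale, initialized at the log-log solution.  The reported
    standard error is sqrt(Σ(E − Ê)² / (n − 2)).
    """
    rho = np.asarray(rho, dtype=float)
    e = np.asarray(e, dtype=float)
    if rho.shape != e.shape or rho.ndim != 1:
        raise InputError("rho and e must be 1-D arrays of equal length")
    if rho.size < 3:
        raise InputError("power-law fit needs at least 3 specimens")
    if np.any(rho <= 0) or np.any(e <= 0):
        raise InputError("densities and moduli must be positive")

    a0, b0 = _loglog_ols(rho, e)
    if method == "log-log-ols":
        a, b = a0, b0
    elif method == "nonlinear-ls":
        from scipy.optimize import curve_fit

        try:
            popt, _ = curve_fit(
                lambda r, a, b: a * r**b,
                rho,
                e,
                p0=[a0, b0],
                maxfev=20000,
                xtol=1e-10,
                ftol=1e-10,
            )
        except RuntimeError as exc:
            raise FitError(f"nonlinear power-law fit did not converge: {exc}") from exc
        a, b = float(popt[0]), float(popt[1])
        if not (np.isfinite(a) and np.isfinite(b)) or a <= 0:
            raise FitError(f"nonlinear fit produced invalid parameters a={a}, b={b}")
    else:
        raise InputError(f"unknown fit method {method!r}")

    resid = e - a * rho**b
    dof = max(rho.size - 2, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof))
    return PowerLawModel(a, b, standard_error=se, fit_method=method)


def eval_power_law(model: PowerLawModel, rho) -> float | np.ndarray:
    """Predicted modulus a·ρ^b (MPa); ρ must be positive."""
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr <= 0):
        raise InputError("density must be positive")
    out = model.coefficient * rho_arr**model.exponent
    return float(out) if np.isscalar(rho) or rho_arr.ndim == 0 else out


@dataclass
class CalibrationReport:
    """Per-specimen power-law diagnostics.

    ``table`` has one row per (included) specimen with predicted modulus and
    squared residual; ``standard_error`` aggregates the residuals;
    ``sensitivity`` maps each specimen id to the aggregate standard error
    recomputed with that specimen left out.
    """

    table: "pandas.DataFrame"
    standard_error: float
    se_formula: str
    excluded: tuple[str, ...] = ()
    sensitivity: dict[str, float] = field(default_factory=dict)


_SE_FORMULAS = {
    "rms-n-2": lambda ssr, n: math.sqrt(ssr / (n - 2)) if n > 2 else float("nan"),
    "rms-n": lambda ssr, n: math.sqrt(ssr / n),
    "rms-n-1": lambda ssr, n: math.sqrt(ssr / (n - 1)) if n > 1 else float("nan"),
}


def calibration_report(
    model: PowerLawModel,
    specimens: Sequence[SpecimenRecord],
    exclude: Sequence[str] | None = None,
    se_formula: str = "rms-n-2",
    leave_one_out: bool = True,
) -> CalibrationReport:
    """Evaluate a power law against measured (ρ, E) specimen data.

    For each specimen: predicted E = a·ρ^b and the squared residual
    (E_measured − E_predicted)².  The aggregate standard error formula is
    configurable (``rms-n-2`` default).  With ``leave_one_out`` the standard
    error is also recomputed dropping each specimen in turn, which exposes
    single-specimen outliers (a slipped specimen dominates the residual sum).
    """
    import pandas as pd

    if se_formula not in _SE_FORMULAS:
        raise InputError(
            f"unknown se_formula {se_formula!r}; options: {sorted(_SE_FORMULAS)}"
        )
    excluded = tuple(str(x) for x in (exclude or ()))
    kept = [s for s in specimens if str(s.specimen_id) not in excluded]
    if not kept:
        raise InputError("no specimens left after exclusion")
    for s in kept:
        if s.ash_density is None or s.modulus is None:
            raise InputError(f"{s.specimen_id}: needs ash_density and modulus")

    rho = np.array([s.ash_density for s in kept], dtype=float)
    e_meas = np.array([s.modulus for s in kept], dtype=float)
    e_pred = eval_power_law(model, rho)
    resid = (e_meas - e_pred) ** 2
    table = pd.DataFrame(
        {
            "specimen_id": [str(s.specimen_id) for s in kept],
            "ash_density": rho,
            "e_measured": e_meas,
            "e_predicted": e_pred,
            "residual": resid,
        }
    )
    se_fn = _SE_FORMULAS[se_formula]
    se = se_fn(float(resid.sum()), len(kept))

    sensitivity: dict[str, float] = {}
    if leave_one_out and len(kept) > 3:
        for i, s in enumerate(kept):
            ssr = float(resid.sum() - resid[i])
            sensitivity[str(s.specimen_id)] = se_fn(ssr, len(kept) - 1)

    return CalibrationReport(
        table=table,
        standard_error=se,
        se_formula=se_formula,
        excluded=excluded,
        sensitivity=sensitivity,
    )
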