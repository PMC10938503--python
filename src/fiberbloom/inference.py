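"""Convert absorbance measurements to bloomed fractions and fit release models.

The measurement chain: fiber pieces are washed in a known solvent
volume, the dissolved additive is quantified by UV-vis absorbance via
the Beer-Lambert law, and the result is expressed as the fraction ``w``
of the initially loaded additive that has left the fiber interior.
Two fits are provided:

* a power law ``w = a * t**n`` estimated by ordinary least squares of
  ln w on ln t (the log-log linearization used for release data, whose
  exponent near 0.5 signals diffusion-limited transport), and
* the diffusion-limited cylinder model, a one-parameter nonlinear fit
  for the diffusion coefficient ``D`` (full eigenseries, or its
  square-root-of-time leading term).

Points at or above a released-fraction cutoff (default w = 0.85) are
excluded from both fits: late in release the accessible free surface
shrinks and the ideal-cylinder model degrades.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .diffusion import (
    FiberGeometry,
    ReleaseCurve,
    TransportParameters,
    dimensionless_state,
    release_fraction,
)

__all__ = [
    "BeerLambertCalibration",
    "FiberSample",
    "BloomObservation",
    "PowerLawFitResult",
    "DiffusionFitResult",
    "absorbance_to_moles",
    "bloomed_fraction",
    "fit_power_law",
    "fit_diffusion_coefficient",
    "predict_curve",
]

#: default released-fraction cutoff for fitting
DEFAULT_MAX_W = 0.85
#: search box for the diffusion coefficient, cm^2/s
D_BOUNDS = (1e-16, 1e-4)

# effective density of a 1:2 LDPE(0.925):HDPE(0.952) blend by weight
DEFAULT_DENSITY_G_CM3 = 0.943
# molar mass of ROY, C12H9N3O2S
ROY_MOLAR_MASS_G_MOL = 259.28


@dataclass(frozen=True)
class BeerLambertCalibration:
    """A = epsilon * c * l calibration for quantifying the dissolved additive."""

    molar_absorptivity: float  # M^-1 cm^-1 at the stated wavelength
    path_length_cm: float = 1.0
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if self.molar_absorptivity <= 0 or self.path_length_cm <= 0:
            raise ValueError("calibration constants must be positive")


@dataclass(frozen=True)
class FiberSample:
    """Everything needed to turn dissolved moles into a released fraction."""

    geometry: FiberGeometry
    loading_wt_frac: float
    density_g_cm3: float = DEFAULT_DENSITY_G_CM3
    molar_mass_g_mol: float = ROY_MOLAR_MASS_G_MOL
    n_pieces: int = 1
    solvent_volume_L: float = 0.003

    def __post_init__(self) -> None:
        if not 0 < self.loading_wt_frac < 1:
            raise ValueError("loading_wt_frac must be in (0, 1)")
        for name in ("density_g_cm3", "molar_mass_g_mol", "n_pieces", "solvent_volume_L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def additive_mass_g(self) -> float:
        """Mass of additive initially loaded across all fiber pieces."""
        g = self.geometry
        volume = math.pi * g.radius_cm**2 * g.length_cm * self.n_pieces
        return volume * self.density_g_cm3 * self.loading_wt_frac

    @property
    def additive_moles(self) -> float:
        return self.additive_mass_g / self.molar_mass_g_mol


@dataclass
class BloomObservation:
    """One wash measurement: a time plus absorbance and/or released fraction."""

    time_s: float
    absorbance: float | None = None
    fraction_w: float | None = None
    exclude_flag: bool = False
    exclude_reason: str = ""

    def __post_init__(self) -> None:
        if self.absorbance is None and self.fraction_w is None:
            raise ValueError("need at least one of absorbance / fraction_w")
        if self.fraction_w is not None and not 0 <= self.fraction_w <= 1.05:
            raise ValueError("fraction_w outside [0, 1.05]")


@dataclass(frozen=True)
class PowerLawFitResult:
    exponent: float
    prefactor: float
    residual_rms: float
    n_points_used: int
    n_excluded: int = 0


@dataclass(frozen=True)
class DiffusionFitResult:
    diffusion_coeff_cm2_s: float
    stderr: float
    residual_rms: float
    fit_range_max_w: float
    n_points_used: int
    n_excluded: int = 0
    mode: str = "series"
    converged: bool = True
    message: str = ""


def absorbance_to_moles(
    absorbance: float, calibration: BeerLambertCalibration, volume_L: float
) -> float:
    """Moles of additive in solution from a Beer-Lambert absorbance reading."""
    if absorbance < 0:
        raise ValueError("absorbance must be non-negative")
    if volume_L <= 0:
        raise ValueError("volume_L must be positive")
    conc_M = absorbance / (calibration.molar_absorptivity * calibration.path_length_cm)
    return conc_M * volume_L


def bloomed_fraction(moles: float, sample: FiberSample) -> float:
    """Released fraction w = dissolved moles / initially loaded moles.

    Values above 1.05 trigger a data-quality warning (measurement
    overshoot), never an error.
    """
    if moles < 0:
        raise ValueError("moles must be non-negative")
    loaded = sample.additive_moles
    if loaded <= 0:
        raise ValueError("sample holds no additive mass")
    w = moles / loaded
    if w > 1.05:
        warnings.warn(
            f"released fraction w = {w:.3f} exceeds 1.05; check calibration "
            "or sample accounting",
            stacklevel=2,
        )
    return w


def _usable(curve: ReleaseCurve, max_w: float, positive: bool) -> tuple[np.ndarray, np.ndarray, int]:
    t = curve.times_s
    w = curve.fractions
    keep = w < max_w
    if positive:
        keep &= (w > 0) & (t > 0)
    else:
        keep &= w >= 0
    return t[keep], w[keep], int((~keep).sum())


def fit_power_law(curve: ReleaseCurve, max_w: float = DEFAULT_MAX_W) -> PowerLawFitResult:
    """OLS fit of ln w = n ln t + ln a over points with 0 < w < max_w.

    The exponent is dimensionless; the prefactor carries units of w per
    (time unit)**exponent, so it rescales (but the exponent does not)
    when times are expressed in hours instead of seconds.
    """
    t, w, n_excl = _usable(curve, max_w, positive=True)
    if t.size < 3:
        raise ValueError(
            f"need >= 3 usable points with 0 < w < {max_w}, have {t.size}"
        )
    slope, intercept = np.polyfit(np.log(t), np.log(w), 1)
    resid = np.log(w) - (slope * np.log(t) + intercept)
    return PowerLawFitResult(
        exponent=float(slope),
        prefactor=float(np.exp(intercept)),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points_used=int(t.size),
        n_excluded=n_excl,
    )


def predict_curve(
    params: TransportParameters,
    geometry: FiberGeometry,
    times_s: np.ndarray,
) -> ReleaseCurve:
    """Forward model: released fraction at the given times."""
    times_s = np.asarray(times_s, dtype=float)
    taus = np.array(
        [dimensionless_state(params, geometry, t).tau for t in times_s]
    )
    eta = dimensionless_state(params, geometry, 0.0).eta
    w = np.atleast_1d(release_fraction(taus, eta=eta))
    return ReleaseCurve(times_s=times_s, fractions=w)


def _model_w(log10_D: float, t: np.ndarray, R: float, mode: str) -> np.ndarray:
    D = 10.0**log10_D
    tau = D * t / R**2
    if mode == "sqrt_term":
        return (4.0 / math.sqrt(math.pi)) * np.sqrt(tau)
    return np.atleast_1d(release_fraction(tau))


def fit_diffusion_coefficient(
    curve: ReleaseCurve,
    geometry: FiberGeometry,
    max_w: float = DEFAULT_MAX_W,
    mode: str = "series",
) -> DiffusionFitResult:
    """Estimate D by nonlinear least squares on w (not ln w).

    ``mode='series'`` fits the full diffusion-limited eigenseries;
    ``mode='sqrt_term'`` fits only the leading w = (4/sqrt(pi)) sqrt(D t / R^2)
    behavior.  D is searched in log space within a physically sensible
    box (1e-16, 1e-4) cm^2/s; the standard error comes from the
    Jacobian at the optimum.
    """
    if mode not in ("series", "sqrt_term"):
        raise ValueError(f"unknown mode {mode!r}")
    t, w, n_excl = _usable(curve, max_w, positive=True)
    if t.size < 3:
        raise ValueError(f"need >= 3 usable points below w = {max_w}, have {t.size}")
    R = geometry.radius_cm

    def resid(p: np.ndarray) -> np.ndarray:
        return _model_w(p[0], t, R, mode) - w

    # crude initialization from the sqrt-t law at the median point
    mid = t.size // 2
    D0 = (w[mid] * math.sqrt(math.pi) / 4.0) ** 2 * R**2 / t[mid]
    D0 = min(max(D0, D_BOUNDS[0] * 10), D_BOUNDS[1] / 10)
    sol = optimize.least_squares(
        resid,
        x0=[math.log10(D0)],
        bounds=([math.log10(D_BOUNDS[0])], [math.log10(D_BOUNDS[1])]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    D_hat = 10.0 ** sol.x[0]
    r = sol.fun
    dof = max(t.size - 1, 1)
    sigma2 = float(r @ r) / dof
    J = sol.jac
    JtJ = float((J.T @ J)[0, 0])
    if JtJ > 0:
        se_log10 = math.sqrt(sigma2 / JtJ)
        stderr = D_hat * math.log(10.0) * se_log10
    else:
        stderr = math.nan
    return DiffusionFitResult(
        diffusion_coeff_cm2_s=D_hat,
        stderr=stderr,
        residual_rms=float(np.sqrt(np.mean(r**2))),
        fit_range_max_w=max_w,
        n_points_used=int(t.size),
        n_excluded=n_excl,
        mode=mode,
        converged=bool(sol.success),
        message=str(sol.message),
    )
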