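"""Enzyme characterization arithmetic for peroxidase variants.

Specific activity from the veratraldehyde absorbance slope (Beer-Lambert,
ε310 = 9.3 mM⁻¹cm⁻¹), enzyme concentration from the heme Soret band
(ε409 = 168 mM⁻¹cm⁻¹), first-order thermal-inactivation constants from the
log-linear decay of residual activity with t½ = ln2/kd, and
Michaelis-Menten saturation fits for kcat and KM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import ContractViolation, FitConvergenceError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssayConstants:
    """Extinction coefficients and path length of the photometric assays."""

    epsilon_product: float = 9.3    # veratraldehyde at 310 nm, mM⁻¹ cm⁻¹
    epsilon_soret: float = 168.0    # heme Soret band at 409 nm, mM⁻¹ cm⁻¹
    path_cm: float = 1.0

    def __post_init__(self) -> None:
        if min(self.epsilon_product, self.epsilon_soret, self.path_cm) <= 0:
            raise ValueError("assay constants must be positive")


DEFAULT_CONSTANTS = AssayConstants()


def specific_activity(
    abs_slope: float,
    enzyme_mass_mg: float,
    volume_ml: float = 1.0,
    constants: AssayConstants = DEFAULT_CONSTANTS,
) -> float:
    """Specific activity in U mg⁻¹ (µmol product per minute per mg enzyme).

    ``abs_slope`` is the absorbance increase in A min⁻¹; one unit converts
    1 µmol substrate per minute, so the product formation rate is
    slope/(ε·l) mM min⁻¹ times the reaction volume in ml (mM·ml = µmol).
    """
    if abs_slope < 0:
        raise ContractViolation(f"negative absorbance slope {abs_slope}")
    if enzyme_mass_mg <= 0 or volume_ml <= 0:
        raise ContractViolation("enzyme mass and reaction volume must be positive")
    rate_umol_min = abs_slope / (constants.epsilon_product * constants.path_cm) * volume_ml
    return rate_umol_min / enzyme_mass_mg


def enzyme_concentration(
    a409: float, constants: AssayConstants = DEFAULT_CONSTANTS
) -> float:
    """Holoenzyme concentration (mM) from the Soret-band absorbance."""
    if a409 < 0:
        raise ContractViolation("negative absorbance")
    return a409 / (constants.epsilon_soret * constants.path_cm)


# ---------------------------------------------------------------------------
# Thermal inactivation
# ---------------------------------------------------------------------------


@dataclass
class ActivityTimeSeries:
    """Residual activity (fraction of t = 0) versus incubation time (min)."""

    times_min: np.ndarray
    activities: np.ndarray
    temperature: str = ""

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, float)
        self.activities = np.asarray(self.activities, float)
        if len(self.times_min) != len(self.activities):
            raise ValueError("times and activities length mismatch")
        if (self.times_min < 0).any() or (np.diff(self.times_min) <= 0).any():
            raise ValueError("times must be non-negative and increasing")


@dataclass
class DeactivationFit:
    """First-order inactivation constant with regression diagnostics."""

    kd: float               # min⁻¹
    kd_se: float
    r2: float
    n_used: int
    n_excluded: int
    negative_kd_warning: bool

    @property
    def half_life_min(self) -> float:
        return half_life(self.kd)

    def kd_ci95(self) -> tuple[float, float]:
        t = stats.t.ppf(0.975, self.n_used - 2)
        return (self.kd - t * self.kd_se, self.kd + t * self.kd_se)


def fit_deactivation(series: ActivityTimeSeries) -> DeactivationFit:
    """kd from OLS of ln(residual activity) on time.

    Activities are normalized to the t = 0 measurement before the log
    regression; non-positive activities are excluded with a logged count.
    A rising series yields a negative kd, reported with a warning flag.
    """
    t, a = series.times_min, series.activities
    if t[0] != 0:
        raise ContractViolation("series must start at t = 0 for normalization")
    if a[0] <= 0:
        raise ContractViolation("t = 0 activity must be positive")
    a = a / a[0]
    keep = a > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d non-positive activities from the log fit", n_excluded)
    t, a = t[keep], a[keep]
    if len(t) < 3:
        raise ContractViolation("need >= 3 positive-activity points")
    res = stats.linregress(t, np.log(a))
    kd = -float(res.slope)
    return DeactivationFit(
        kd=kd, kd_se=float(res.stderr), r2=float(res.rvalue) ** 2,
        n_used=len(t), n_excluded=n_excluded, negative_kd_warning=kd < 0,
    )


def half_life(kd: float) -> float:
    """t½ = ln 2 / kd (min for kd in min⁻¹)."""
    if kd <= 0:
        raise ContractViolation(f"half-life undefined for kd = {kd} <= 0")
    return math.log(2) / kd


def fold_improvement(t_half_variant: float, t_half_reference: float) -> float:
    """Half-life ratio of a variant over a reference enzyme."""
    if t_half_variant <= 0 or t_half_reference <= 0:
        raise ContractViolation("half-lives must be positive")
    return t_half_variant / t_half_reference


# ---------------------------------------------------------------------------
# Michaelis-Menten
# ---------------------------------------------------------------------------


@dataclass
class SaturationSeries:
    """Initial rates versus substrate concentration (µM)."""

    concentrations_uM: np.ndarray
    rates: np.ndarray       # specific activity or s⁻¹ scale
    temperature: str = ""

    def __post_init__(self) -> None:
        self.concentrations_uM = np.asarray(self.concentrations_uM, float)
        self.rates = np.asarray(self.rates, float)
        if len(self.concentrations_uM) != len(self.rates):
            raise ValueError("concentration/rate length mismatch")
        if (self.concentrations_uM <= 0).any():
            raise ValueError("substrate concentrations must be positive")
        if (self.rates < 0).any():
            raise ValueError("rates must be non-negative")


@dataclass
class MichaelisMentenFit:
    """Saturation-fit estimates with asymptotic standard errors."""

    vmax: float
    km_uM: float
    vmax_se: float
    km_se: float
    kcat: float | None = None          # s⁻¹, when enzyme concentration given
    kcat_over_km: float | None = None
    km_at_boundary: bool = False


def fit_michaelis_menten(
    series: SaturationSeries,
    enzyme_conc_uM: float | None = None,
    km_floor_uM: float = 1e-6,
) -> MichaelisMentenFit:
    """Nonlinear least-squares fit of v = Vmax·S/(KM + S).

    Starting values: Vmax at the largest observed rate, KM at the
    concentration nearest half-maximal rate; both parameters bounded
    positive.  A KM estimate collapsing onto the lower bound (saturated
    data) is flagged rather than treated as a genuine estimate.
    """
    s, v = series.concentrations_uM, series.rates
    if len(s) < 4:
        raise ContractViolation("need >= 4 concentration points")
    vmax0 = float(v.max())
    if vmax0 <= 0:
        raise ContractViolation("all rates are zero")
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2))])
    p0 = (vmax0, max(km0, km_floor_uM))
    try:
        popt, pcov = optimize.curve_fit(
            lambda S, vmax, km: vmax * S / (km + S), s, v, p0=p0,
            bounds=([0.0, km_floor_uM], [np.inf, np.inf]), maxfev=20000,
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"Michaelis-Menten fit did not converge (start Vmax={p0[0]:g}, KM={p0[1]:g})"
        ) from exc
    vmax, km = float(popt[0]), float(popt[1])
    se = np.sqrt(np.diag(pcov))
    # a KM far below the assayed concentration span is not resolvable:
    # the data are saturated and the estimate sits on the lower boundary
    fit = MichaelisMentenFit(
        vmax=vmax, km_uM=km, vmax_se=float(se[0]), km_se=float(se[1]),
        km_at_boundary=km <= max(km_floor_uM * 10, 0.01 * float(s.min())),
    )
    if enzyme_conc_uM is not None:
        if enzyme_conc_uM <= 0:
            raise ContractViolation("enzyme concentration must be positive")
        fit.kcat = vmax / enzyme_conc_uM
        fit.kcat_over_km = fit.kcat / km
    return fit
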