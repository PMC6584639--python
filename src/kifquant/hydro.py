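"""Hydrodynamic sizing from calibrated elution experiments.

Size-exclusion chromatography (SEC) reports the Stokes radius ``Rs`` of a
particle through its elution volume; rate-zonal (glycerol-gradient)
centrifugation reports its sedimentation coefficient ``S``. Both are read off
linear calibrations against standard proteins:

- SEC:      log10(Rs)  =  slope · (Ve − V0)  +  intercept
- gradient: S          =  slope · v          +  intercept

The two observables combine into a molecular weight by the Siegel–Monty
relation ``M = 4205 · Rs[nm] · S[Svedberg]`` (Daltons), and into a shape
descriptor, the frictional ratio ``f/f_min = S_max / S`` with
``S_max = 0.00361 · M^(2/3)`` — the sedimentation coefficient of an ideal
unhydrated sphere of the same mass. ``f/f_min`` near 1 means compact;
larger values mean elongated.

Uncertainties combine the calibration-fit standard errors with a
peak-location error of half the fraction spacing, by first-order propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

SIEGEL_MONTY_COEF = 4205.0  # Da per (nm · Svedberg)
SMAX_COEF = 0.00361  # Svedberg per Da^(2/3)

__all__ = [
    "CalibrationStandard",
    "CalibrationLine",
    "ElutionProfile",
    "HydrodynamicResult",
    "CalibrationError",
    "NoPeakError",
    "NonPhysicalError",
    "fit_calibration",
    "locate_peak",
    "invert_calibration",
    "molecular_weight",
    "s_max",
    "frictional_ratio",
    "analyze_sample",
]


class CalibrationError(ValueError):
    """Raised when a calibration line cannot be fitted."""


class NoPeakError(ValueError):
    """Raised when an elution profile has no interior peak."""


class NonPhysicalError(ValueError):
    """Raised when an inverted calibration yields a non-positive quantity."""


@dataclass(frozen=True)
class CalibrationStandard:
    """A standard protein anchoring the calibration.

    ``anchor_value`` is the Stokes radius in nm (SEC mode) or the
    sedimentation coefficient in Svedberg (gradient mode);
    ``elution_volume`` is Ve − V0 in ml (SEC) or ml from the gradient top.
    """

    name: str
    anchor_value: float
    elution_volume: float

    def __post_init__(self) -> None:
        if self.anchor_value <= 0:
            raise ValueError(f"anchor_value must be > 0, got {self.anchor_value}")
        if self.elution_volume < 0:
            raise ValueError(f"elution_volume must be >= 0, got {self.elution_volume}")


@dataclass(frozen=True)
class CalibrationLine:
    slope: float
    intercept: float
    transform: str  # "log10_anchor" (SEC) or "identity_anchor" (gradient)
    slope_se: float = 0.0
    intercept_se: float = 0.0
    r_squared: float = 1.0
    n_points: int = 2

    def __post_init__(self) -> None:
        if self.transform not in ("log10_anchor", "identity_anchor"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise CalibrationError("non-finite calibration line")


@dataclass
class ElutionProfile:
    """Signal per fraction along an elution coordinate (ml)."""

    volumes: np.ndarray
    signal: np.ndarray
    salt_mm: float | None = None
    assay: str = ""

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.volumes.shape != self.signal.shape:
            raise ValueError("volumes and signal must have equal length")
        if self.volumes.size < 5:
            raise ValueError("need >= 5 fractions for peak fitting")
        if np.any(np.diff(self.volumes) <= 0):
            raise ValueError("volumes must be strictly increasing")

    @property
    def fraction_ml(self) -> float:
        return float(np.median(np.diff(self.volumes)))


@dataclass
class HydrodynamicResult:
    rs_nm: float
    rs_se: float
    s_svedberg: float
    s_se: float
    mw_da: float
    mw_se: float
    f_ratio: float
    f_ratio_se: float
    flags: list = field(default_factory=list)


def fit_calibration(standards, transform: str = "log10_anchor") -> CalibrationLine:
    """Ordinary least squares of the (transformed) anchor on elution volume.

    SEC mode regresses log10(Rs) on Ve − V0; gradient mode regresses S on
    volume-from-top. Returns the line with standard errors.
    """
    standards = list(standards)
    if len(standards) < 2:
        raise CalibrationError("need at least 2 calibration standards")
    v = np.array([s.elution_volume for s in standards], dtype=float)
    if np.ptp(v) == 0:
        raise CalibrationError("standards have identical elution volumes")
    a = np.array([s.anchor_value for s in standards], dtype=float)
    if transform == "log10_anchor":
        y = np.log10(a)
    elif transform == "identity_anchor":
        y = a
    else:
        raise ValueError(f"unknown transform {transform!r}")
    res = stats.linregress(v, y)
    r2 = float(res.rvalue**2) if len(standards) > 2 else 1.0
    return CalibrationLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        transform=transform,
        slope_se=float(res.stderr) if math.isfinite(res.stderr) else 0.0,
        intercept_se=float(res.intercept_stderr)
        if math.isfinite(res.intercept_stderr)
        else 0.0,
        r_squared=r2,
        n_points=len(standards),
    )


def _gaussian(v, amp, mu, sig, base):
    return base + amp * np.exp(-0.5 * ((v - mu) / sig) ** 2)


def locate_peak(profile: ElutionProfile, window: int = 3) -> tuple[float, float]:
    """Locate the elution peak as (volume_ml, uncertainty_ml).

    Fits a Gaussian to the ±``window`` fractions around the maximal fraction;
    falls back to an intensity-weighted centroid of the window if the fit
    fails. The reported uncertainty is never below half the fraction spacing,
    the resolution limit of fraction collection.
    """
    y = profile.signal
    v = profile.volumes
    if np.all(np.diff(y) >= 0) or np.all(np.diff(y) <= 0):
        raise NoPeakError("profile is monotone; no interior peak")
    imax = int(np.argmax(y))
    # symmetric two-point tie -> midpoint
    ties = np.flatnonzero(y == y[imax])
    if ties.size > 1 and np.all(np.diff(ties) == 1):
        imax_center = 0.5 * (ties[0] + ties[-1])
    else:
        imax_center = float(imax)
    if imax == 0 or imax == y.size - 1:
        # boundary maximum: warn via flag semantics by raising only if monotone
        pass
    lo = max(0, imax - window)
    hi = min(y.size, imax + window + 1)
    vw, yw = v[lo:hi], y[lo:hi]
    half = profile.fraction_ml / 2.0
    mu0 = float(np.interp(imax_center, np.arange(v.size), v))
    try:
        import warnings

        base0 = float(yw.min())
        p0 = [float(y[imax] - base0), mu0, profile.fraction_ml, base0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(_gaussian, vw, yw, p0=p0, maxfev=5000)
        mu = float(popt[1])
        mu_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else half
        if not (vw[0] - profile.fraction_ml <= mu <= vw[-1] + profile.fraction_ml):
            raise RuntimeError("fit centre outside window")
    except (RuntimeError, ValueError):
        w = yw - yw.min()
        mu = float(np.sum(vw * w) / np.sum(w)) if np.sum(w) > 0 else mu0
        mu_se = half
    return mu, max(mu_se, half)


def invert_calibration(
    line: CalibrationLine, elution_volume: float, volume_se: float = 0.0
) -> tuple[float, float]:
    """Map an elution volume back to the anchor quantity (Rs or S) ± SE."""
    if not math.isfinite(elution_volume):
        raise ValueError("elution volume must be finite")
    y = line.slope * elution_volume + line.intercept
    # variance of the line value at v, plus the peak-location term
    var_y = (
        (elution_volume * line.slope_se) ** 2
        + line.intercept_se**2
        + (line.slope * volume_se) ** 2
    )
    if line.transform == "log10_anchor":
        value = 10.0**y
        se = value * math.log(10.0) * math.sqrt(var_y)
    else:
        value = y
        se = math.sqrt(var_y)
        if value <= 0:
            raise NonPhysicalError(
                f"gradient calibration gives S = {value:.3g} <= 0 at v = {elution_volume}"
            )
    return float(value), float(se)


def molecular_weight(rs_nm: float, s_svedberg: float) -> float:
    """Siegel–Monty molecular weight M = 4205 · Rs · S, in Daltons."""
    if rs_nm <= 0 or s_svedberg <= 0:
        raise ValueError("Rs and S must be positive")
    return SIEGEL_MONTY_COEF * rs_nm * s_svedberg


def s_max(mw_da: float) -> float:
    """Sedimentation coefficient of the equivalent ideal sphere."""
    if mw_da <= 0:
        raise ValueError("molecular weight must be positive")
    return SMAX_COEF * mw_da ** (2.0 / 3.0)


def frictional_ratio(s_svedberg: float, mw_da: float) -> float:
    """f/f_min = S_max(M) / S; 1 for a compact sphere, >1 for elongated."""
    if s_svedberg <= 0:
        raise ValueError("S must be positive")
    return s_max(mw_da) / s_svedberg


def analyze_sample(
    sec_line: CalibrationLine,
    sec_profile: ElutionProfile,
    grad_line: CalibrationLine,
    grad_profile: ElutionProfile,
    expected_mass_da: float | None = None,
) -> HydrodynamicResult:
    """Full inference: peak locations -> Rs and S -> MW and frictional ratio.

    The frictional ratio uses ``expected_mass_da`` if given (the sequence-based
    mass of the assembled species), otherwise the inferred MW.
    """
    v_sec, dv_sec = locate_peak(sec_profile)
    v_grad, dv_grad = locate_peak(grad_profile)
    rs, rs_se = invert_calibration(sec_line, v_sec, dv_sec)
    s, s_se = invert_calibration(grad_line, v_grad, dv_grad)
    mw = molecular_weight(rs, s)
    mw_se = mw * math.sqrt((rs_se / rs) ** 2 + (s_se / s) ** 2)
    mass_for_shape = expected_mass_da if expected_mass_da else mw
    fr = frictional_ratio(s, mass_for_shape)
    if expected_mass_da:
        fr_se = fr * (s_se / s)
    else:
        fr_se = fr * math.sqrt((2.0 / 3.0 * mw_se / mw) ** 2 + (s_se / s) ** 2)
    flags = []
    if fr < 1.0:
        flags.append("f_ratio < 1: inconsistent Rs/S inputs")
    if not (1.0 <= rs <= 20.0):
        flags.append(f"Rs = {rs:.2f} nm outside the expected 1-20 nm range")
    if not (1.0 <= s <= 30.0):
        flags.append(f"S = {s:.2f} outside the expected 1-30 S range")
    return HydrodynamicResult(
        rs_nm=rs,
        rs_se=rs_se,
        s_svedberg=s,
        s_se=s_se,
        mw_da=mw,
        mw_se=mw_se,
        f_ratio=fr,
        f_ratio_se=fr_se,
        flags=flags,
    )
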