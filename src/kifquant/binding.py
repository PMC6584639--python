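"""Binding-affinity fitting and microtubule-decoration quantification.

Titration experiments (e.g. microscale thermophoresis of a fluorescent
receptor against a serially diluted ligand) are fitted with the quadratic
(ligand-depletion) isotherm. For total receptor R, total ligand L and
dissociation constant Kd, the bound receptor fraction is the physical root
of the binding quadratic,

    fb = ((R + L + Kd) - sqrt((R + L + Kd)^2 - 4 R L)) / (2 R),

which reduces to the familiar hyperbola L / (L + Kd) as R -> 0. The
measured signal is modelled as
``f_free + (f_bound - f_free) * fb`` and fitted by nonlinear least squares
with Kd log-parameterised.

The decoration assay measures how strongly a motor coats microtubules: the
mean intensity along each hand-traced microtubule line ROI minus a local
background region gives a per-microtubule corrected intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "BindingSeries",
    "KdFit",
    "DecorationMeasurement",
    "NonIdentifiableError",
    "bound_fraction",
    "fit_kd",
    "decoration_intensity",
]


class NonIdentifiableError(ValueError):
    """Raised when a titration carries no usable binding transition."""


@dataclass
class BindingSeries:
    """A ligand titration: total ligand per point (µM) and signal (AU)."""

    ligand_um: np.ndarray
    signal: np.ndarray
    receptor_um: float = 0.05

    def __post_init__(self) -> None:
        self.ligand_um = np.asarray(self.ligand_um, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.ligand_um.shape != self.signal.shape:
            raise ValueError("ligand and signal must have equal length")
        if self.ligand_um.size < 6:
            raise ValueError("need >= 6 titration points")
        if np.any(self.ligand_um <= 0):
            raise ValueError("ligand concentrations must be positive")
        if np.unique(self.ligand_um).size != self.ligand_um.size:
            raise ValueError("ligand concentrations must be distinct")


@dataclass
class KdFit:
    kd_um: float
    f_free: float
    f_bound: float
    rss: float
    se_kd_um: float
    model: str = "quadratic"
    flags: list = field(default_factory=list)


@dataclass
class DecorationMeasurement:
    mean_intensity: float
    local_background: float
    flags: list = field(default_factory=list)

    @property
    def corrected(self) -> float:
        return self.mean_intensity - self.local_background


def bound_fraction(ligand_um, receptor_um, kd_um):
    """Bound receptor fraction under the quadratic (depletion) isotherm.

    Evaluated in the algebraically equivalent form
    ``2L / (A + sqrt(A^2 - 4 R L))`` with ``A = R + L + Kd``, which is
    numerically stable down to (and including) R = 0, where it becomes the
    hyperbolic L / (L + Kd). Vectorised over ``ligand_um``.
    """
    L = np.asarray(ligand_um, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand must be >= 0")
    if receptor_um < 0:
        raise ValueError("receptor must be >= 0")
    if kd_um <= 0:
        raise ValueError("Kd must be > 0")
    A = receptor_um + L + kd_um
    disc = A * A - 4.0 * receptor_um * L
    if np.any(disc < -1e-9 * np.max(A * A)):
        raise FloatingPointError("negative discriminant in binding quadratic")
    fb = 2.0 * L / (A + np.sqrt(np.clip(disc, 0.0, None)))
    return float(fb) if np.isscalar(ligand_um) else fb


def fit_kd(series: BindingSeries, model: str = "quadratic") -> KdFit:
    """Nonlinear least-squares Kd fit of a titration series.

    Fits (log Kd, f_free, f_bound). Kd is initialised at the mid-transition
    ligand concentration; the plateaux initialise from the signals at the
    lowest and highest ligand points. ``model`` selects the quadratic
    (default) or the R->0 hyperbolic isotherm.
    """
    if model not in ("quadratic", "hyperbolic"):
        raise ValueError(f"unknown model {model!r}")
    L = series.ligand_um
    y = series.signal
    if np.max(L) / np.min(L) < 10.0:
        raise ValueError("titration must span at least one decade of ligand")
    spread = float(np.ptp(y))
    scale = max(float(np.mean(np.abs(y))), 1e-12)
    if spread < 1e-9 * scale:
        raise NonIdentifiableError("flat titration: no binding transition")
    order = np.argsort(L)
    f_free0 = float(y[order[0]])
    f_bound0 = float(y[order[-1]])
    mid = 0.5 * (f_free0 + f_bound0)
    kd0 = float(np.interp(mid, y[order], L[order])) if f_bound0 != f_free0 else 1.0
    kd0 = min(max(kd0, np.min(L) / 10), np.max(L) * 10)
    R = series.receptor_um if model == "quadratic" else 0.0

    def resid(theta):
        log_kd, f_free, f_bound = theta
        fb = bound_fraction(L, R, math.exp(log_kd))
        return f_free + (f_bound - f_free) * fb - y

    res = optimize.least_squares(
        resid, [math.log(kd0), f_free0, f_bound0], method="lm", max_nfev=5000
    )
    kd = float(math.exp(res.x[0]))
    rss = float(np.sum(res.fun**2))
    dof = max(L.size - 3, 1)
    s2 = rss / dof
    try:
        jtj_inv = np.linalg.inv(res.jac.T @ res.jac)
        se_log_kd = math.sqrt(max(s2 * jtj_inv[0, 0], 0.0))
        se_kd = kd * se_log_kd
    except np.linalg.LinAlgError:
        se_kd = math.nan
    flags = []
    f_free, f_bound = float(res.x[1]), float(res.x[2])
    if abs(f_bound - f_free) < 3 * math.sqrt(s2):
        flags.append("plateau separation within noise: Kd weakly identified")
    return KdFit(
        kd_um=kd,
        f_free=f_free,
        f_bound=f_bound,
        rss=rss,
        se_kd_um=se_kd,
        model=model,
        flags=flags,
    )


def _roi_pixels(image: np.ndarray, roi) -> np.ndarray:
    """Pixel values under an ROI: a boolean mask or an (N, 2) polyline of
    (row, col) vertices rasterised with 1-px-wide segments."""
    roi = np.asarray(roi)
    if roi.dtype == bool:
        return image[roi]
    from skimage.draw import line

    rr_all, cc_all = [], []
    pts = np.round(roi).astype(int)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("polyline ROI must be an (N, 2) array of (row, col)")
    if len(pts) == 1:
        rr_all, cc_all = [pts[0, 0]], [pts[0, 1]]
    for a, b in zip(pts[:-1], pts[1:]):
        rr, cc = line(a[0], a[1], b[0], b[1])
        rr_all.extend(rr)
        cc_all.extend(cc)
    rr = np.clip(np.asarray(rr_all), 0, image.shape[0] - 1)
    cc = np.clip(np.asarray(cc_all), 0, image.shape[1] - 1)
    return image[rr, cc]


def decoration_intensity(image, mt_rois, bg_rois) -> list[DecorationMeasurement]:
    """Local-background-corrected mean intensity per microtubule.

    ``mt_rois`` and ``bg_rois`` are paired lists (one background region per
    microtubule) of boolean masks or (row, col) polylines. A corrected
    intensity below zero is kept but flagged, since it can only arise from
    noise.
    """
    image = np.asarray(image, dtype=float)
    mt_rois, bg_rois = list(mt_rois), list(bg_rois)
    if len(mt_rois) != len(bg_rois):
        raise ValueError("each microtubule ROI needs a paired background ROI")
    out = []
    for mt, bg in zip(mt_rois, bg_rois):
        m = float(np.mean(_roi_pixels(image, mt)))
        b = float(np.mean(_roi_pixels(image, bg)))
        flags = ["corrected intensity < 0 (noise)"] if m - b < 0 else []
        out.append(DecorationMeasurement(mean_intensity=m, local_background=b, flags=flags))
    return out
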