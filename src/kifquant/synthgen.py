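"""Seeded synthetic-data generators with known ground truth.

Every downstream analysis in this package is validated closed-loop: data
are simulated under the statistical model the analysis assumes, with the
generative parameters returned alongside, and the analysis must recover
them. The generators emulate:

- bleach-step counts from a dimer/tetramer mixture with independent
  GFP-activity thinning (invisible k = 0 spots are redrawn, mirroring that
  TIRF only scores fluorescent spots);
- piecewise-constant photobleaching traces with exponential dwell times and
  Gaussian camera noise (defaults follow a 0.5 s / 600 s acquisition);
- Poisson motor landings on a microtubule with truncated-normal speeds and
  exponential run lengths, truncated at the plus end (with an optional
  accumulate-at-end mode), rendered into noisy kymographs through a
  symmetric Gaussian PSF;
- Gaussian elution peaks placed exactly on linear hydrodynamic calibration
  relations;
- quadratic-isotherm titration series built with the standard twofold
  dilution / 4:1 mixing scheme (37 µM stock -> 29.6 µM top ligand, 50 nM
  receptor) and multiplicative noise;
- two-channel cell images with tail/cytoplasm/background regions, and
  disc-shaped podosome objects with a configurable actin-coincident subset.

All generators are pure functions of (parameters, seed): identical inputs
give bit-identical outputs. No camera physics (EM gain, shot noise) or 3D
optics are modelled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage.draw import disk

from .binding import BindingSeries, bound_fraction
from .bleachsteps import BleachTrace, StepHistogram
from .cellimage import DEFAULT_PIXEL_SIZE_UM, RegionMasks, TwoChannelImage
from .hydro import CalibrationLine, CalibrationStandard, ElutionProfile
from .motility import KymographImage, Track

logger = logging.getLogger(__name__)

__all__ = [
    "MotilityGroundTruth",
    "WILD_TYPE_MOTILITY",
    "sim_bleach_counts",
    "sim_bleach_trace",
    "sim_motility",
    "render_kymograph",
    "sim_elution",
    "sim_binding_series",
    "sim_cell_image",
    "default_region_masks",
    "sim_podosome_image",
    "SEC_STANDARDS",
    "GRADIENT_STANDARDS",
    "SEC_LINE",
    "GRADIENT_LINE",
]

# Standard-protein anchors used for hydrodynamic calibration
SEC_STANDARDS = (
    CalibrationStandard("thyroglobulin", 8.5, 0.0),
    CalibrationStandard("apoferritin", 6.1, 0.0),
    CalibrationStandard("catalase", 5.2, 0.0),
    CalibrationStandard("BSA", 3.48, 0.0),
)
GRADIENT_STANDARDS = (
    CalibrationStandard("apoferritin", 17.6, 0.0),
    CalibrationStandard("catalase", 11.3, 0.0),
    CalibrationStandard("glucose oxidase", 8.0, 0.0),
    CalibrationStandard("BSA", 4.6, 0.0),
)
# log10(Rs) vs (Ve - V0);  S vs volume-from-gradient-top
SEC_LINE = CalibrationLine(-0.014, 0.97, "log10_anchor")
GRADIENT_LINE = CalibrationLine(5.66, -3.92, "identity_anchor")


@dataclass(frozen=True)
class MotilityGroundTruth:
    """Generative parameters of a single-molecule motility condition."""

    landing_rate_true: float  # events / (µm · min)
    speed_mean: float  # µm/s
    speed_sd: float  # µm/s
    runlength_mean: float  # µm
    static_fraction: float  # in [0, 1]
    static_dwell_s: float = 20.0

    def __post_init__(self) -> None:
        if min(self.landing_rate_true, self.speed_mean, self.speed_sd,
               self.runlength_mean, self.static_dwell_s) < 0:
            raise ValueError("rates, speeds and lengths must be >= 0")
        if not 0.0 <= self.static_fraction <= 1.0:
            raise ValueError("static_fraction must be in [0, 1]")


#: Wild-type KIF1C-GFP single-molecule regime: 0.45 µm/s mean speed,
#: 8.6 µm mean run length; landing rate and static fraction chosen as
#: typical for sparse sub-nanomolar TIRF assays.
WILD_TYPE_MOTILITY = MotilityGroundTruth(
    landing_rate_true=0.15,
    speed_mean=0.45,
    speed_sd=0.12,
    runlength_mean=8.6,
    static_fraction=0.3,
)


# ---------------------------------------------------------------------------
# photobleaching


def sim_bleach_counts(x: float, p: float, n_motors: int, seed: int) -> StepHistogram:
    """Bleach-step histogram of ``n_motors`` detected spots.

    Each motor is a tetramer with probability ``x``, else a dimer; the
    visible step count is Binomial(4 or 2, p). Motors with zero active GFPs
    are undetectable and are redrawn until ``n_motors`` visible spots have
    accumulated, so the emitted histogram follows the detection-conditioned
    (k >= 1) mixed binomial.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must be in [0,1], got {x}")
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0,1], got {p}")
    if n_motors < 1:
        raise ValueError("n_motors must be >= 1")
    rng = np.random.default_rng(seed)
    counts = {k: 0 for k in range(1, 5)}
    remaining = n_motors
    while remaining > 0:
        batch = max(remaining * 2, 16)
        n_gfp = np.where(rng.random(batch) < x, 4, 2)
        k = rng.binomial(n_gfp, p)
        k = k[k >= 1][:remaining]
        for kk in k:
            counts[int(kk)] += 1
        remaining -= k.size
    return StepHistogram(counts)


def sim_bleach_trace(
    k_steps: int,
    unit_intensity: float = 100.0,
    noise_sd: float = 20.0,
    mean_dwell: float = 60.0,
    frame_interval: float = 0.5,
    n_frames: int = 1200,
    seed: int = 0,
) -> BleachTrace:
    """Piecewise-constant bleach trace with ``k_steps`` downward steps.

    Starts at ``k_steps * unit_intensity``; each fluorophore bleaches after
    an independent Exponential(``mean_dwell``) time, dropping the level by
    one unit. i.i.d. Gaussian noise is added. Ground-truth step times are
    attached to the returned trace (steps beyond the acquisition window are
    recorded but produce no level change in the data).
    """
    if k_steps < 0:
        raise ValueError("k_steps must be >= 0")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    if n_frames <= 0:
        raise ValueError("n_frames must be > 0")
    rng = np.random.default_rng(seed)
    step_times = np.sort(rng.exponential(mean_dwell, size=k_steps))
    t = np.arange(n_frames) * frame_interval
    level = unit_intensity * (k_steps - np.searchsorted(step_times, t, side="right"))
    noise = rng.normal(0.0, noise_sd, size=n_frames) if noise_sd > 0 else 0.0
    return BleachTrace(
        frame_interval=frame_interval,
        intensities=level + noise,
        step_times=step_times,
    )


# ---------------------------------------------------------------------------
# motility


def _truncated_normal_positive(rng, mean, sd, size):
    out = rng.normal(mean, sd, size=size)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def sim_motility(
    mt_length_um: float,
    duration_min: float,
    truth: MotilityGroundTruth = WILD_TYPE_MOTILITY,
    seed: int = 0,
    end_behavior: str = "truncate",
    end_dwell_s: float = 20.0,
    sample_dt_s: float = 0.1,
) -> tuple[list[Track], list[dict]]:
    """Simulate motor landings on one microtubule.

    Landings follow a Poisson process at ``landing_rate_true * mt_length``;
    positions are uniform along the microtubule. A landing is static with
    probability ``static_fraction`` (dwelling an exponential time), else the
    motor runs plus-end-directed at a truncated-normal speed for an
    exponential run length, truncated at the plus end. ``end_behavior``
    selects whether a motor reaching the end detaches (``"truncate"``) or
    pauses there for ``end_dwell_s`` (``"accumulate"``). Run lengths cut
    short by the microtubule end or the movie end are marked censored.

    Returns sampled tracks plus a per-event ground-truth log.
    """
    if mt_length_um <= 0 or duration_min <= 0:
        raise ValueError("mt_length and duration must be > 0")
    if end_behavior not in ("truncate", "accumulate"):
        raise ValueError(f"unknown end_behavior {end_behavior!r}")
    rng = np.random.default_rng(seed)
    T = duration_min * 60.0
    n = rng.poisson(truth.landing_rate_true * mt_length_um * duration_min)
    tracks: list[Track] = []
    events: list[dict] = []
    t_land = np.sort(rng.uniform(0.0, T, size=n))
    x_land = rng.uniform(0.0, mt_length_um, size=n)
    is_static = rng.random(n) < truth.static_fraction
    speeds = _truncated_normal_positive(rng, truth.speed_mean, truth.speed_sd, n)
    runlens = rng.exponential(truth.runlength_mean, size=n) if n else np.array([])
    dwells = rng.exponential(truth.static_dwell_s, size=n)
    for i in range(n):
        t0, x0 = float(t_land[i]), float(x_land[i])
        if is_static[i]:
            t1 = min(t0 + float(dwells[i]), T)
            censored = t1 >= T
            ts = np.unique(np.append(np.arange(t0, t1, sample_dt_s), t1))
            xs = np.full_like(ts, x0)
            run_obs = 0.0
        else:
            v = float(speeds[i])
            L_true = float(runlens[i])
            avail = mt_length_um - x0
            end_censored = L_true >= avail
            run_geom = min(L_true, avail)
            t_run_end = t0 + run_geom / v
            if end_behavior == "accumulate" and end_censored:
                t_detach = t_run_end + float(rng.exponential(end_dwell_s))
            else:
                t_detach = t_run_end
            t1 = min(t_detach, T)
            censored = end_censored or (t_run_end >= T)
            ts = np.unique(np.append(np.arange(t0, t1, sample_dt_s), t1))
            xs = x0 + v * np.clip(ts - t0, 0.0, t_run_end - t0)
            run_obs = float(xs[-1] - x0)
        if ts.size < 2:
            ts = np.array([t0, min(t0 + sample_dt_s, T)])
            xs = np.array([x0, xs[-1] if len(np.atleast_1d(xs)) else x0])
        tracks.append(
            Track(
                track_id=i,
                t_s=ts,
                x_um=xs,
                is_static=bool(is_static[i]),
                censored=bool(censored),
            )
        )
        events.append(
            {
                "track_id": i,
                "t_land_s": t0,
                "x_land_um": x0,
                "static": bool(is_static[i]),
                "speed_um_s": 0.0 if is_static[i] else float(speeds[i]),
                "runlength_true_um": 0.0 if is_static[i] else float(runlens[i]),
                "runlength_observed_um": run_obs,
                "censored": bool(censored),
            }
        )
    return tracks, events


def render_kymograph(
    tracks,
    mt_length_um: float,
    duration_s: float,
    pixel_nm: float = 105.0,
    frame_s: float = 0.1,
    psf_sigma_px: float = 1.3,
    signal: float = 100.0,
    noise_sd: float = 20.0,
    seed: int = 0,
) -> KymographImage:
    """Render tracks into a kymograph (rows = frames, columns = position).

    Each track deposits a Gaussian-blurred spot of amplitude ``signal`` at
    its interpolated position in every frame it spans; additive Gaussian
    background noise completes the image. Track portions outside the imaged
    region are clipped (and logged).
    """
    if pixel_nm <= 0 or frame_s <= 0:
        raise ValueError("pixel_nm and frame_s must be > 0")
    rng = np.random.default_rng(seed)
    n_rows = int(round(duration_s / frame_s))
    n_cols = int(math.ceil(mt_length_um * 1000.0 / pixel_nm)) + 1
    img = np.zeros((n_rows, n_cols))
    half_w = max(int(math.ceil(4 * psf_sigma_px)), 1)
    px_um = pixel_nm / 1000.0
    for tr in tracks:
        f0 = max(int(math.ceil(tr.t_s[0] / frame_s)), 0)
        f1 = min(int(math.floor(tr.t_s[-1] / frame_s)), n_rows - 1)
        if f1 < f0:
            continue
        frames = np.arange(f0, f1 + 1)
        xs = np.interp(frames * frame_s, tr.t_s, tr.x_um)
        cols = xs / px_um
        if np.any(cols < -1) or np.any(cols > n_cols):
            logger.warning("track %s exceeds image bounds; clipped", tr.track_id)
            cols = np.clip(cols, 0.0, n_cols - 1.0)
        base = np.floor(cols).astype(int)
        for dk in range(-half_w, half_w + 2):
            cc = base + dk
            ok = (cc >= 0) & (cc < n_cols)
            if not np.any(ok):
                continue
            w = np.exp(-0.5 * ((cc[ok] - cols[ok]) / psf_sigma_px) ** 2)
            np.add.at(img, (frames[ok], cc[ok]), signal * w)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return KymographImage(pixels=img, pixel_nm=pixel_nm, frame_s=frame_s)


# ---------------------------------------------------------------------------
# elution profiles


def sim_elution(
    line: CalibrationLine,
    standards,
    sample_anchor: float,
    peak_width_ml: float = 0.4,
    fraction_ml: float | None = None,
    n_fractions: int | None = None,
    noise_sd: float = 0.0,
    amplitude: float = 100.0,
    seed: int = 0,
):
    """Elution profiles whose peak centres sit exactly on a calibration line.

    ``standards`` are :class:`~kifquant.hydro.CalibrationStandard` whose
    ``elution_volume`` is ignored: the centre of each species (standards and
    the sample with ``sample_anchor`` — an Rs for SEC lines, an S for
    gradient lines) is the calibration-line preimage of its anchor value.
    Returns ``(profiles, truth)`` where ``profiles`` maps species name to
    :class:`ElutionProfile` (the sample is ``"sample"``) and ``truth`` maps
    name to the exact peak centre in ml.
    """
    if fraction_ml is None:
        fraction_ml = 0.5 if line.transform == "log10_anchor" else 0.2
    rng = np.random.default_rng(seed)

    def centre(anchor: float) -> float:
        y = math.log10(anchor) if line.transform == "log10_anchor" else anchor
        return (y - line.intercept) / line.slope

    anchors = {s.name: s.anchor_value for s in standards}
    anchors["sample"] = sample_anchor
    centres = {name: centre(a) for name, a in anchors.items()}
    vmax = max(centres.values()) + 4 * max(peak_width_ml, fraction_ml)
    if n_fractions is None:
        n_fractions = int(math.ceil(vmax / fraction_ml)) + 1
    volumes = np.arange(n_fractions) * fraction_ml
    if any(not (volumes[0] <= c <= volumes[-1]) for c in centres.values()):
        raise ValueError("a peak centre falls outside the profiled volume range")
    profiles = {}
    for name, c in centres.items():
        if peak_width_ml > 0:
            sig = amplitude * np.exp(-0.5 * ((volumes - c) / peak_width_ml) ** 2)
        else:  # delta-like single-fraction peak
            sig = np.zeros_like(volumes)
            sig[int(np.argmin(np.abs(volumes - c)))] = amplitude
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)
        profiles[name] = ElutionProfile(volumes=volumes.copy(), signal=sig,
                                        assay=line.transform)
    return profiles, centres


# ---------------------------------------------------------------------------
# binding series


def sim_binding_series(
    kd_um: float,
    receptor_um: float = 0.05,
    stock_um: float = 37.0,
    n_dilutions: int = 16,
    dilution_factor: float = 2.0,
    mix_fraction: float = 0.8,
    f_free: float = 800.0,
    f_bound: float = 400.0,
    noise_cv: float = 0.0,
    seed: int = 0,
):
    """Titration series from the standard MST dilution/mixing scheme.

    A ``stock_um`` ligand stock is serially diluted ``dilution_factor``-fold
    into ``n_dilutions`` points, then mixed 4:1 with the receptor so each
    final ligand concentration is ``mix_fraction`` of its dilution (top
    point = 37 x 0.8 = 29.6 µM by default) while the receptor is constant.
    The signal follows the quadratic isotherm between the ``f_free`` and
    ``f_bound`` plateaux with multiplicative Gaussian noise of CV
    ``noise_cv``. Returns ``(series, truth)``.
    """
    if kd_um <= 0:
        raise ValueError("Kd must be > 0")
    rng = np.random.default_rng(seed)
    L = stock_um * mix_fraction / dilution_factor ** np.arange(n_dilutions)
    fb = bound_fraction(L, receptor_um, kd_um)
    sig = f_free + (f_bound - f_free) * fb
    if noise_cv > 0:
        sig = sig * (1.0 + rng.normal(0.0, noise_cv, size=sig.shape))
    series = BindingSeries(ligand_um=L, signal=sig, receptor_um=receptor_um)
    truth = {"kd_um": kd_um, "f_free": f_free, "f_bound": f_bound,
             "bound_fraction": fb}
    return series, truth


# ---------------------------------------------------------------------------
# cell images


def default_region_masks(shape=(128, 128)) -> RegionMasks:
    """Disjoint tail / cytoplasm / background masks for synthetic cells."""
    tail = np.zeros(shape, dtype=bool)
    cyto = np.zeros(shape, dtype=bool)
    bg = np.zeros(shape, dtype=bool)
    rr, cc = disk((shape[0] // 4, shape[1] // 4), 8, shape=shape)
    tail[rr, cc] = True
    rr, cc = disk((3 * shape[0] // 4, 3 * shape[1] // 4), 12, shape=shape)
    cyto[rr, cc] = True
    bg[2:12, shape[1] - 12 : shape[1] - 2] = True
    return RegionMasks(tail=tail, cytoplasm=cyto, background=bg)


def sim_cell_image(
    tail_I,
    cyto_I,
    bg_I,
    masks: RegionMasks | None = None,
    noise_sd: float = 0.0,
    shape=(128, 128),
    seed: int = 0,
):
    """Two-channel cell image with region means and Gaussian noise.

    ``tail_I``, ``cyto_I`` and ``bg_I`` are per-channel pairs (channel 0 =
    GFP construct, channel 1 = mCherry control); scalars are broadcast to
    both channels. Returns ``(image, truth)`` with the exact generative
    enrichment ratio per channel.
    """
    if masks is None:
        masks = default_region_masks(shape)
    shape = masks.tail.shape
    rng = np.random.default_rng(seed)

    def pair(v):
        return (float(v), float(v)) if np.isscalar(v) else (float(v[0]), float(v[1]))

    tail_I, cyto_I, bg_I = pair(tail_I), pair(cyto_I), pair(bg_I)
    channels = []
    for c in range(2):
        img = np.full(shape, bg_I[c])
        img[masks.cytoplasm] = cyto_I[c]
        img[masks.tail] = tail_I[c]
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=shape)
        channels.append(img)
    truth = {
        "ratio_per_channel": tuple(
            (tail_I[c] - bg_I[c]) / (cyto_I[c] - bg_I[c])
            if cyto_I[c] != bg_I[c]
            else math.nan  # undefined ratio; the analysis side must raise
            for c in range(2)
        )
    }
    return TwoChannelImage(channels=tuple(channels)), truth


def sim_podosome_image(
    n_objects: int,
    radius_px: float = 3.0,
    object_I: float = 100.0,
    bg_I: float = 10.0,
    coloc_fraction: float = 1.0,
    image_size=(128, 128),
    noise_sd: float = 0.0,
    seed: int = 0,
    max_tries: int = 10_000,
):
    """Disc-shaped podosomes in a two-channel image with known ground truth.

    Channel 0 (cortactin) contains discs at all object positions; channel 1
    (actin) only at a ``coloc_fraction`` subset — the actin-coincidence
    filter of the counting routine should accept exactly that subset.
    Placement is by rejection sampling so discs never overlap. Returns
    ``(image, truth)`` with positions, areas and coincidence flags.
    """
    if n_objects < 0:
        raise ValueError("n_objects must be >= 0")
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    margin = radius_px + 2
    min_sep = 2 * radius_px + 3
    centres: list[tuple[float, float]] = []
    tries = 0
    while len(centres) < n_objects:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place non-overlapping podosomes")
        r = rng.uniform(margin, image_size[0] - margin)
        c = rng.uniform(margin, image_size[1] - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centres):
            centres.append((r, c))
    n_coinc = int(round(coloc_fraction * n_objects))
    coincident = np.zeros(n_objects, dtype=bool)
    if n_coinc:
        coincident[rng.choice(n_objects, size=n_coinc, replace=False)] = True
    cort = np.full(image_size, bg_I)
    act = np.full(image_size, bg_I)
    areas = []
    for i, (r, c) in enumerate(centres):
        rr, cc = disk((r, c), radius_px, shape=image_size)
        cort[rr, cc] = object_I
        areas.append(int(rr.size))
        if coincident[i]:
            act[rr, cc] = object_I
    if noise_sd > 0:
        cort = cort + rng.normal(0.0, noise_sd, size=image_size)
        act = act + rng.normal(0.0, noise_sd, size=image_size)
        cort = np.clip(cort, 0.0, None)
        act = np.clip(act, 0.0, None)
    image = TwoChannelImage(channels=(cort, act),
                            pixel_size_um=DEFAULT_PIXEL_SIZE_UM)
    truth = {
        "centres": centres,
        "areas_px": areas,
        "coincident": coincident.tolist(),
        "n_coincident": int(coincident.sum()),
    }
    return image, truth
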