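"""Per-track and population inference from passive-motion trajectories.

Lateral (gravity-perpendicular) displacements give the diffusivity and,
through the Einstein–Stokes relation, the hydrodynamic radius; axial
displacement gives the sedimentation velocity and, through Stokes' law,
the particle–fluid density difference; together they give the particle
Strouhal number.  Estimates are made per particle — the Strouhal
number's r^-4 sensitivity means population averages of raw tracks mix
very different regimes — and only then summarized.

Conventions: lateral drift must be subtracted before diffusivity
estimation (see :func:`passivemotion.tracking.subtract_drift`); axial
drift is the signal and is never subtracted.  Sinking is positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .physics import (FluidMedium, MissionEnvironment,
                      density_diff_from_velocity, radius_from_diffusivity,
                      strouhal, ParticleSpec, motion_regime)
from .tracking import Track

__all__ = [
    "TrackEstimate",
    "PopulationSummary",
    "msd_diffusivity",
    "walker_diffusivity",
    "walker_diameters",
    "z_velocity",
    "population_z_drift",
    "estimate_particle",
    "estimate_population",
    "filter_outliers",
    "summarize",
]

logger = logging.getLogger(__name__)

#: minimum track points for any per-track estimate
MIN_TRACK_POINTS = 2


@dataclass
class TrackEstimate:
    """Derived quantities for one track (SI units; NaN where a stage
    could not run, with the reason in ``flags``)."""

    track_id: int
    n_steps: int
    D: float = math.nan            # diffusivity, m^2/s
    r: float = math.nan            # hydrodynamic radius, m
    v_z: float = math.nan          # axial velocity, m/s (sinking positive)
    delta_rho: float = math.nan    # particle - fluid density, kg/m^3
    sr: float = math.nan           # particle Strouhal number
    regime: str = ""
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class PopulationSummary:
    """Location/spread summary of one estimated quantity over a
    population: mean, median, Student-t 95% CI half-width of the mean
    (NaN when n < 2), count, and histogram."""

    quantity: str
    mean: float
    median: float
    ci95_half_width: float
    n: int
    bin_edges: np.ndarray
    counts: np.ndarray


# ---------------------------------------------------------------------------
# Diffusivity
# ---------------------------------------------------------------------------

def msd_diffusivity(track: Track, dims: int = 2, max_lag: int = 3
                    ) -> float:
    """Diffusivity from a short-lag MSD fit (m^2/s).

    The mean squared displacement at lags 1..``max_lag`` is fit by an
    unweighted straight line through the origin and the slope divided by
    ``2 * dims``.  ``dims = 1`` uses x only; ``dims = 2`` uses x and y.
    Short lags keep the estimate in the regime where the MSD of an
    (overdamped, drift-subtracted) trajectory is linear and the lag
    covariance manageable; ``max_lag = 3`` is the default compromise.

    Returns NaN (with a log warning) if the track is shorter than
    ``max_lag + 1`` points.
    """
    if dims not in (1, 2):
        raise ValueError(f"dims must be 1 or 2, got {dims}")
    if max_lag < 1:
        raise ValueError(f"max_lag must be >= 1, got {max_lag}")
    if len(track) < max_lag + 1:
        logger.warning("track %s too short for MSD (%d points, need %d)",
                       track.track_id, len(track), max_lag + 1)
        return math.nan
    coords = [track.x] if dims == 1 else [track.x, track.y]
    if any(c is None for c in coords):
        raise ValueError("track lacks the coordinates for the requested dims")
    # lags live on the frame-index grid so gaps keep their true lag
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    f = track.frames
    contiguous = bool(np.all(np.diff(f) == 1))
    idx = None if contiguous else {fr: j for j, fr in enumerate(f)}
    for i, k in enumerate(lags):
        if contiguous:
            sq = sum(np.sum((c[k:] - c[:-k]) ** 2) for c in coords)
            n_pairs = len(f) - k
        else:
            sq = 0.0
            n_pairs = 0
            for j, fr in enumerate(f):
                j2 = idx.get(fr + k)
                if j2 is None:
                    continue
                for c in coords:
                    sq += (c[j2] - c[j]) ** 2
                n_pairs += 1
        msd[i] = sq / n_pairs if n_pairs else math.nan
    taus = lags * track.dt
    ok = ~np.isnan(msd)
    if not ok.any():
        logger.warning("track %s has no valid MSD lags", track.track_id)
        return math.nan
    slope = float(np.sum(msd[ok] * taus[ok]) / np.sum(taus[ok] ** 2))
    return slope / (2.0 * dims)


def walker_diffusivity(track: Track) -> float:
    """Maximum-likelihood diffusivity from 2D step lengths (m^2/s).

    For pure 2D Brownian motion the squared single-frame step length is
    exponentially distributed with mean ``4 D dt``, so the MLE of D is
    the mean squared step over ``4 dt``.
    """
    if track.y is None:
        raise ValueError("walker diffusivity needs both lateral coordinates")
    if len(track) < MIN_TRACK_POINTS:
        return math.nan
    consecutive = np.flatnonzero(np.diff(track.frames) == 1)
    if consecutive.size == 0:
        return math.nan
    dx = track.x[consecutive + 1] - track.x[consecutive]
    dy = track.y[consecutive + 1] - track.y[consecutive]
    return float(np.mean(dx**2 + dy**2) / (4.0 * track.dt))


def walker_diameters(tracks: list[Track], fluid: FluidMedium,
                     bin_width: float = 0.1e-6
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-track hydrodynamic diameters by step-length MLE, histogrammed.

    Each usable track contributes one maximum-likelihood diffusivity
    (:func:`walker_diffusivity`) converted to a diameter
    ``d = k_B T / (3 pi eta D)``; the diameters are binned at
    ``bin_width`` (default 0.1 µm).  Returns ``(diameters, bin_edges,
    counts)`` with diameters in metres.
    """
    diameters = []
    for tr in tracks:
        D = walker_diffusivity(tr)
        if not math.isfinite(D) or D <= 0:
            logger.warning("track %s skipped in Walker sizing", tr.track_id)
            continue
        diameters.append(2.0 * radius_from_diffusivity(D, fluid))
    diameters = np.asarray(diameters)
    if diameters.size == 0:
        raise ValueError("no usable tracks for Walker sizing")
    hi = (math.floor(diameters.max() / bin_width) + 1) * bin_width
    edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(diameters, bins=edges)
    return diameters, edges, counts


# ---------------------------------------------------------------------------
# Axial velocity and density
# ---------------------------------------------------------------------------

def z_velocity(track: Track) -> float:
    """Axial velocity as the OLS slope of z versus time (m/s, sinking
    positive).  OLS over the whole track beats the endpoint difference
    on variance for long tracks."""
    if track.z is None:
        raise ValueError("track has no axial coordinate")
    if len(track) < MIN_TRACK_POINTS:
        return math.nan
    t = track.t
    tc = t - t.mean()
    denom = float(np.sum(tc**2))
    if denom == 0.0:
        return math.nan
    return float(np.sum(tc * track.z) / denom)


def population_z_drift(tracks: list[Track]) -> float:
    """Ensemble axial drift: mean per-track OLS velocity weighted by
    track length (m/s).  Length weighting lets long, well-determined
    tracks dominate, mimicking a pooled regression."""
    if not tracks:
        raise ValueError("need at least one track")
    vs, ws = [], []
    for tr in tracks:
        v = z_velocity(tr)
        if math.isfinite(v):
            vs.append(v)
            ws.append(len(tr))
    if not vs:
        return math.nan
    return float(np.average(vs, weights=ws))


# ---------------------------------------------------------------------------
# Per-particle chain
# ---------------------------------------------------------------------------

def estimate_particle(track: Track, fluid: FluidMedium,
                      env: MissionEnvironment,
                      radius_source: str = "diffusivity",
                      fixed_radius: float | None = None,
                      dims: int = 2, max_lag: int = 3) -> TrackEstimate:
    """Full per-track inference chain.

    Lateral MSD -> diffusivity -> radius (or a fixed, externally known
    radius), axial OLS -> velocity -> density difference (inverse
    Stokes), then the Strouhal number of the estimated particle.  Stages
    that cannot run leave NaN and append a reason code to ``flags``;
    the function is deterministic given the track.
    """
    if radius_source not in ("diffusivity", "fixed"):
        raise ValueError(f"radius_source must be 'diffusivity' or 'fixed', "
                         f"got {radius_source!r}")
    est = TrackEstimate(track_id=track.track_id, n_steps=max(len(track) - 1, 0))

    if track.y is not None:
        D = msd_diffusivity(track, dims=dims, max_lag=max_lag)
        if math.isfinite(D) and D > 0:
            est.D = D
        else:
            est.flags.append("diffusivity-failed")
    else:
        est.flags.append("no-lateral-coordinates")

    if radius_source == "fixed":
        if fixed_radius is None or fixed_radius <= 0:
            raise ValueError("fixed radius_source requires fixed_radius > 0")
        est.r = float(fixed_radius)
    elif math.isfinite(est.D):
        est.r = radius_from_diffusivity(est.D, fluid)
    else:
        est.flags.append("radius-unavailable")

    if track.z is not None:
        v = z_velocity(track)
        if math.isfinite(v):
            est.v_z = v
        else:
            est.flags.append("z-velocity-failed")
    else:
        est.flags.append("no-axial-coordinate")

    if math.isfinite(est.v_z) and math.isfinite(est.r):
        est.delta_rho = density_diff_from_velocity(est.v_z, est.r, env)
        particle = ParticleSpec(radius=est.r,
                                density=max(fluid.density + est.delta_rho,
                                            np.finfo(float).tiny),
                                label="estimated")
        est.sr = strouhal(particle, env)
        est.regime = motion_regime(est.sr)
    else:
        est.flags.append("density-unavailable")
    return est


def estimate_population(tracks: list[Track], fluid: FluidMedium,
                        env: MissionEnvironment,
                        subtract_lateral_drift: bool = True,
                        **kwargs) -> list[TrackEstimate]:
    """Estimate every track, after optional ensemble lateral drift
    subtraction (the recommended default)."""
    from .tracking import estimate_drift, subtract_drift
    if subtract_lateral_drift and any(tr.y is not None for tr in tracks):
        tracks = subtract_drift(tracks, estimate_drift(tracks))
    return [estimate_particle(tr, fluid, env, **kwargs) for tr in tracks]


# ---------------------------------------------------------------------------
# Filtering and summaries
# ---------------------------------------------------------------------------

_QUANTITIES = {"D": "D", "diffusivity": "D", "r": "r", "radius": "r",
               "v_z": "v_z", "delta_rho": "delta_rho", "sr": "sr",
               "strouhal": "sr"}

#: default diffusivity outlier cutoff (m^2/s): 1.20 µm^2/s, well above
#: the Einstein value of any plausible particle in the tracked size range
DEFAULT_D_CUTOFF = 1.20e-12


def filter_outliers(estimates: list[TrackEstimate], quantity: str = "D",
                    cutoff: float = DEFAULT_D_CUTOFF) -> list[TrackEstimate]:
    """Drop estimates whose |quantity| exceeds the cutoff.

    Gross diffusivity outliers arise from tracking errors (identity
    switches, double detections); a hard cutoff on D is the standard
    cleanup before histogramming.  NaN values are kept — they carry
    their own flags.  The number removed is logged.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    try:
        attr = _QUANTITIES[quantity]
    except KeyError:
        raise ValueError(
            f"unknown quantity {quantity!r}; one of {sorted(_QUANTITIES)}"
        ) from None
    kept = [e for e in estimates
            if not (math.isfinite(getattr(e, attr))
                    and abs(getattr(e, attr)) > cutoff)]
    removed = len(estimates) - len(kept)
    if removed:
        logger.info("filter_outliers removed %d/%d estimates (%s > %g)",
                    removed, len(estimates), attr, cutoff)
    if not kept:
        logger.warning("all %d estimates removed as outliers", len(estimates))
    return kept


def summarize(estimates: list[TrackEstimate], quantity: str,
              bins: int | np.ndarray = 20) -> PopulationSummary:
    """Mean, median, Student-t 95% CI of the mean, and histogram of one
    estimated quantity over a population (NaN entries excluded).

    Skewed size/diffusivity distributions make the median the more
    representative location statistic; both are reported.
    """
    try:
        attr = _QUANTITIES[quantity]
    except KeyError:
        raise ValueError(
            f"unknown quantity {quantity!r}; one of {sorted(_QUANTITIES)}"
        ) from None
    vals = np.array([getattr(e, attr) for e in estimates], dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no finite values of {quantity!r} to summarize")
    if vals.size >= 2:
        half = float(stats.t.ppf(0.975, vals.size - 1)
                     * vals.std(ddof=1) / math.sqrt(vals.size))
    else:
        half = math.nan
    counts, edges = np.histogram(vals, bins=bins)
    return PopulationSummary(quantity=attr, mean=float(vals.mean()),
                             median=float(np.median(vals)),
                             ci95_half_width=half, n=int(vals.size),
                             bin_edges=edges, counts=counts)


def estimates_frame(estimates: list[TrackEstimate]) -> pd.DataFrame:
    """Estimates as a DataFrame in the estimates-CSV dialect
    (micrometre-scaled columns)."""
    return pd.DataFrame([{
        "track_id": e.track_id,
        "D_um2_s": e.D * 1e12,
        "r_um": e.r * 1e6,
        "vz_um_s": e.v_z * 1e6,
        "delta_rho_kg_m3": e.delta_rho,
        "strouhal": e.sr,
        "n_steps": e.n_steps,
        "flags": ";".join(e.flags),
    } for e in estimates])
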