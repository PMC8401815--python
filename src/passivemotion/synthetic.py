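"""Ground-truthed synthetic recordings of passively moving particles.

Generates populations of spherical particles with known radius and
density, propagates each as an overdamped Langevin trajectory — exact
Gaussian Brownian increments per frame plus a constant Stokes drift
along z — inside a finite sample chamber, degrades the positions with
Gaussian localization noise, and optionally renders the scene as a 4D
intensity series (TIFF z-stacks per time point) mimicking the output
geometry of a holographic reconstruction.

The default recording emulates the reference instrument: 15 frames/s,
356 µm x 365 µm lateral field, 1 mm deep chamber, 0.8 µm lateral and
2 µm axial optical resolution.  Because Brownian motion is exactly
discretizable, per-frame increments are sampled from their true normal
distribution; there is no integration time-step bias at any frame rate.

Particles that reach the chamber floor or ceiling leave the tracked
ensemble (their track ends there), as particles settling onto a chamber
wall do in a real recording; reflecting walls are available as an
option.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .physics import (FluidMedium, MaterialLibrary, MissionEnvironment,
                      ParticleSpec, diffusion_coefficient, stokes_velocity)
from .tracking import Track

__all__ = [
    "FixedRadius",
    "LognormalSize",
    "ClusterSize",
    "PopulationSpec",
    "RecordingSpec",
    "stage_rng",
    "sample_population",
    "simulate_track",
    "apply_localization_noise",
    "simulate_population",
    "render_volume_series",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent random stream for a named pipeline stage.

    The stage name is hashed (CRC-32) into the seed sequence so that
    every stage draws from its own substream of the single global seed
    and can be rerun independently without perturbing the others.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Size models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedRadius:
    """Monodisperse population: every particle has exactly this radius (m)."""
    radius: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.radius <= 0:
            raise ValueError("radius must be > 0 m")
        return np.full(n, self.radius)


@dataclass(frozen=True)
class LognormalSize:
    """Lognormal radius distribution with a given median radius (m) and
    log-space sigma; the common shape of bead and cell size spreads."""
    median_radius: float
    sigma: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.median_radius <= 0 or self.sigma < 0:
            raise ValueError("median_radius must be > 0 and sigma >= 0")
        return self.median_radius * np.exp(self.sigma * rng.standard_normal(n))


@dataclass(frozen=True)
class ClusterSize:
    """Clusters of identical monomers: diameters are integer multiples of
    the monomer diameter (m), as seen in streptavidin-linked gas-vesicle
    aggregates whose size histogram shows peaks at fixed increments."""
    monomer_diameter: float
    max_multiplicity: int
    probabilities: tuple[float, ...] | None = None

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.monomer_diameter <= 0 or self.max_multiplicity < 1:
            raise ValueError("need monomer_diameter > 0, max_multiplicity >= 1")
        p = self.probabilities
        if p is not None:
            p = np.asarray(p, dtype=float)
            if len(p) != self.max_multiplicity:
                raise ValueError("probabilities must have max_multiplicity entries")
            p = p / p.sum()
        mult = rng.choice(np.arange(1, self.max_multiplicity + 1), size=n, p=p)
        return mult * self.monomer_diameter / 2.0


SizeModel = FixedRadius | LognormalSize | ClusterSize


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """A particle population to simulate: a material from the density
    library, a particle count, a size model and a gravity environment."""
    material: str
    n_particles: int
    size_model: SizeModel
    env: MissionEnvironment

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")


@dataclass(frozen=True)
class RecordingSpec:
    """Acquisition geometry and noise of a simulated recording.

    All lengths in SI metres.  Defaults follow the reference instrument:
    15 fps over 30 s, a 356 µm x 365 µm lateral field, 1 mm chamber
    depth, and localization noise of 0.2 µm laterally / 1.0 µm axially
    (a few-fold below the 0.8 µm / 2 µm optical resolutions, as typical
    for centroid localization of resolved spots).
    """
    frame_rate: float = 15.0
    duration: float = 30.0
    field_xy: tuple[float, float] = (356e-6, 365e-6)
    chamber_depth: float = 1.0e-3
    sigma_xy: float = 0.2e-6
    sigma_z: float = 1.0e-6
    drift_xy: tuple[float, float] = (0.0, 0.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be > 0")
        if self.chamber_depth <= 0:
            raise ValueError("chamber_depth must be > 0 m")
        if self.sigma_xy < 0 or self.sigma_z < 0:
            raise ValueError("localization noise stds must be >= 0")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate)) + 1


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------

def sample_population(spec: PopulationSpec, seed,
                      library: MaterialLibrary | None = None
                      ) -> list[ParticleSpec]:
    """Draw particle radii from the spec's size model and attach the
    material density; deterministic given the seed."""
    rng = _as_rng(seed)
    if library is None:
        library = MaterialLibrary.default()
    density = library.density(spec.material)
    radii = spec.size_model.sample(spec.n_particles, rng)
    if np.any(radii <= 0):
        raise ValueError("size model produced a non-positive radius")
    return [ParticleSpec(radius=float(r), density=density, label=spec.material)
            for r in radii]


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------

def simulate_track(particle: ParticleSpec, rec: RecordingSpec,
                   env: MissionEnvironment, seed,
                   x0: tuple[float, float, float] | None = None,
                   boundary: str = "absorb",
                   d_override: float | None = None,
                   track_id: int = 0) -> Track:
    """Simulate one particle trajectory sampled at the frame rate.

    Per frame the increments are exact: ``dx = sqrt(2 D dt) xi + u_x dt``
    laterally (``u`` the uniform lateral drift) and
    ``dz = v_stokes dt + sqrt(2 D dt) xi`` axially, with ``xi`` standard
    normal.  ``boundary`` controls the chamber floor/ceiling at z = 0 and
    z = chamber_depth: ``"absorb"`` (default) ends the track at the last
    in-chamber position, as a particle settling onto a wall drops out of
    tracking; ``"reflect"`` folds the path back; ``"none"`` ignores the
    walls.  ``d_override`` substitutes the diffusivity (e.g. 0 for a
    pure-drift check); positions are noise-free — see
    :func:`apply_localization_noise`.
    """
    if boundary not in ("absorb", "reflect", "none"):
        raise ValueError(f"boundary must be absorb/reflect/none, got {boundary!r}")
    rng = _as_rng(seed)
    dt = rec.dt
    n_steps = rec.n_frames - 1
    D = diffusion_coefficient(particle.radius, env.fluid) \
        if d_override is None else float(d_override)
    v = stokes_velocity(particle, env)
    if x0 is None:
        x0 = (rec.field_xy[0] / 2, rec.field_xy[1] / 2, rec.chamber_depth / 2)
    sig = np.sqrt(2.0 * D * dt)
    steps = sig * rng.standard_normal((n_steps, 3))
    steps[:, 0] += rec.drift_xy[0] * dt
    steps[:, 1] += rec.drift_xy[1] * dt
    steps[:, 2] += v * dt
    pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)]) + np.asarray(x0)
    x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]

    L = rec.chamber_depth
    if boundary == "reflect":
        m = np.mod(z, 2.0 * L)
        z = np.where(m > L, 2.0 * L - m, m)
    elif boundary == "absorb":
        out = np.flatnonzero((z < 0.0) | (z > L))
        if out.size:
            k = max(int(out[0]), 1)  # keep at least the starting point
            x, y, z = x[:k], y[:k], z[:k]
    frames = np.arange(len(x))
    return Track(track_id=track_id, frames=frames, dt=dt, x=x, y=y, z=z)


def apply_localization_noise(track: Track, rec: RecordingSpec, seed) -> Track:
    """Add independent Gaussian localization noise per coordinate
    (``sigma_xy`` laterally, ``sigma_z`` axially); zero stds return an
    identical copy."""
    rng = _as_rng(seed)
    n = len(track)

    def noisy(arr, sigma):
        if arr is None:
            return None
        if sigma == 0.0:
            return arr.copy()
        return arr + sigma * rng.standard_normal(n)

    return Track(track.track_id, track.frames.copy(), track.dt,
                 x=noisy(track.x, rec.sigma_xy),
                 y=noisy(track.y, rec.sigma_xy),
                 z=noisy(track.z, rec.sigma_z))


def simulate_population(spec: PopulationSpec, rec: RecordingSpec, seed: int,
                        boundary: str = "absorb", noise: bool = True,
                        library: MaterialLibrary | None = None
                        ) -> tuple[list[Track], pd.DataFrame]:
    """Simulate a full recording of one population.

    Radii are drawn from the size model, initial positions uniformly in
    the field and chamber depth, each particle is propagated with
    :func:`simulate_track`, and (by default) localization noise is
    applied.  Returns the tracks plus a ground-truth table (micrometre
    units, matching the truth CSV dialect) with one row per particle:
    ``particle_id, radius_um, density_kg_m3, v_stokes_um_s, x0_um,
    y0_um, z0_um``.
    """
    particles = sample_population(spec, stage_rng(seed, "population"), library)
    pos_rng = stage_rng(seed, "positions")
    sim_rng = stage_rng(seed, "trajectories")
    noise_rng = stage_rng(seed, "localization")
    tracks: list[Track] = []
    truth_rows = []
    for i, p in enumerate(particles):
        x0 = (pos_rng.uniform(0, rec.field_xy[0]),
              pos_rng.uniform(0, rec.field_xy[1]),
              pos_rng.uniform(0, rec.chamber_depth))
        tr = simulate_track(p, rec, spec.env, sim_rng, x0=x0,
                            boundary=boundary, track_id=i)
        if noise:
            tr = apply_localization_noise(tr, rec, noise_rng)
        tracks.append(tr)
        truth_rows.append({
            "particle_id": i,
            "radius_um": p.radius * 1e6,
            "density_kg_m3": p.density,
            "v_stokes_um_s": stokes_velocity(p, spec.env) * 1e6,
            "x0_um": x0[0] * 1e6,
            "y0_um": x0[1] * 1e6,
            "z0_um": x0[2] * 1e6,
        })
    return tracks, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Volume rendering
# ---------------------------------------------------------------------------

def render_volume_series(tracks: Sequence[Track], rec: RecordingSpec,
                         pixel_size: float, z_step: float,
                         lateral_resolution: float = 0.8e-6,
                         axial_resolution: float = 2.0e-6,
                         background: float = 100.0,
                         amplitude: float = 2000.0,
                         shot_noise: bool = True,
                         seed=0) -> np.ndarray:
    """Render tracks as a 4D (t, z, y, x) uint16 intensity series.

    Each in-bounds particle becomes an anisotropic Gaussian blob whose
    lateral and axial sigmas derive from the optical resolutions
    (interpreted as FWHM), over a constant background with optional
    Poisson (shot-like) noise.  Geometry comes from ``rec`` (field and
    chamber depth) discretized at ``pixel_size`` laterally and
    ``z_step`` axially; keep these coarse for tests, since a full
    2048 x 2048 field at 0.17 µm/px is deliberately not the default.
    """
    if not tracks:
        raise ValueError("cannot render an empty track list")
    if pixel_size <= 0 or z_step <= 0:
        raise ValueError("pixel_size and z_step must be > 0 m")
    rng = _as_rng(seed)
    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0))
    sig_xy = lateral_resolution / fwhm
    sig_z = axial_resolution / fwhm
    nx = int(np.ceil(rec.field_xy[0] / pixel_size))
    ny = int(np.ceil(rec.field_xy[1] / pixel_size))
    nz = int(np.ceil(rec.chamber_depth / z_step))
    n_t = int(max(tr.frames.max() for tr in tracks)) + 1

    vols = np.full((n_t, nz, ny, nx), background, dtype=float)
    half_xy = max(int(np.ceil(4 * sig_xy / pixel_size)), 2)
    half_z = max(int(np.ceil(4 * sig_z / z_step)), 2)
    for tr in tracks:
        if tr.y is None or tr.z is None:
            raise ValueError("rendering requires full 3D tracks")
        for f, px, py, pz in zip(tr.frames, tr.x, tr.y, tr.z):
            ix, iy, iz = px / pixel_size, py / pixel_size, pz / z_step
            if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
                continue
            x_lo, x_hi = max(int(ix) - half_xy, 0), min(int(ix) + half_xy + 1, nx)
            y_lo, y_hi = max(int(iy) - half_xy, 0), min(int(iy) + half_xy + 1, ny)
            z_lo, z_hi = max(int(iz) - half_z, 0), min(int(iz) + half_z + 1, nz)
            zz, yy, xx = np.meshgrid(
                (np.arange(z_lo, z_hi) - iz) * z_step,
                (np.arange(y_lo, y_hi) - iy) * pixel_size,
                (np.arange(x_lo, x_hi) - ix) * pixel_size,
                indexing="ij")
            vols[f, z_lo:z_hi, y_lo:y_hi, x_lo:x_hi] += amplitude * np.exp(
                -(xx**2 + yy**2) / (2 * sig_xy**2) - zz**2 / (2 * sig_z**2))
    if shot_noise:
        vols = rng.poisson(vols).astype(float)
    return np.clip(vols, 0, 65535).astype(np.uint16)
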