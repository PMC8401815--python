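"""Closed-form physics of passive micron-scale particle motion in a fluid.

The model treats a small sphere in a quiescent liquid as subject to two
competing transports:

* **Brownian motion**, characterised by the Einstein–Stokes diffusivity
  ``D = k_B T / (6 pi eta r)``, which dominates lateral (gravity-
  perpendicular) displacement and can be used to size the particle;
* **gravitational settling/rising**, characterised by the Stokes terminal
  velocity ``v = 2 (rho_p - rho_f) g r^2 / (9 eta)``, which dominates the
  axial displacement of dense (or buoyant) particles and can be inverted
  for the particle--fluid density difference.

The ratio of the gravitational transit time over one particle radius to
the Brownian time over the same distance defines the particle Strouhal
number ``Sr_p = 3 k_B T / (4 pi |rho_p - rho_f| g r^4)``: ``Sr_p >> 1``
means diffusion-dominated motion, ``Sr_p << 1`` means ballistic
sinking/floating.

All quantities are SI internally (m, s, kg, K, Pa·s); micrometre-scaled
values appear only at I/O boundaries.  Sinking is positive: the ``z``
axis of every formula increases downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "K_B",
    "FluidMedium",
    "ParticleSpec",
    "MissionEnvironment",
    "MaterialLibrary",
    "water_density",
    "water_viscosity",
    "water",
    "load_environments",
    "diffusion_coefficient",
    "radius_from_diffusivity",
    "brownian_time",
    "stokes_velocity",
    "density_diff_from_velocity",
    "gravity_time",
    "strouhal",
    "motion_regime",
    "required_observation_time",
    "strouhal_grid",
]

#: Boltzmann constant (J/K), 2019 SI exact value.
K_B = 1.380649e-23


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluidMedium:
    """A suspending liquid: absolute temperature (K), dynamic viscosity
    (Pa·s) and mass density (kg/m^3)."""

    temperature: float
    viscosity: float
    density: float

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be > 0 Pa*s, got {self.viscosity}")
        if self.density <= 0:
            raise ValueError(f"density must be > 0 kg/m^3, got {self.density}")


@dataclass(frozen=True)
class ParticleSpec:
    """A spherical particle: hydrodynamic radius (m), material density
    (kg/m^3) and an optional material label."""

    radius: float
    density: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0 m, got {self.radius}")
        if self.density <= 0:
            raise ValueError(f"density must be > 0 kg/m^3, got {self.density}")


@dataclass(frozen=True)
class MissionEnvironment:
    """A gravitational environment for planning: body name, surface (or
    ocean-floor) gravitational acceleration g (m/s^2), and the fluid the
    particles are suspended in."""

    name: str
    gravity: float
    fluid: FluidMedium

    def __post_init__(self) -> None:
        if self.gravity <= 0:
            raise ValueError(f"gravity must be > 0 m/s^2, got {self.gravity}")


# ---------------------------------------------------------------------------
# Water properties
# ---------------------------------------------------------------------------

def water_density(temperature: float) -> float:
    """Density of liquid water at atmospheric pressure (kg/m^3).

    Kell's rational polynomial fit in Celsius temperature; adequate for
    the chamber conditions considered here (roughly -10..100 degC).
    """
    t = temperature - 273.15
    num = (999.83952 + 16.945176 * t - 7.9870401e-3 * t**2
           - 46.170461e-6 * t**3 + 105.56302e-9 * t**4
           - 280.54253e-12 * t**5)
    return num / (1.0 + 16.879850e-3 * t)


# IAPWS 2008 viscosity formulation, dilute-gas + residual contributions.
_VISC_T_STAR = 647.096     # K
_VISC_RHO_STAR = 322.0     # kg/m^3
_VISC_H0 = (1.67752, 2.20462, 0.6366564, -0.241605)
_VISC_H1 = np.zeros((6, 7))
_VISC_H1[0, 0] = 5.20094e-1
_VISC_H1[1, 0] = 8.50895e-2
_VISC_H1[2, 0] = -1.08374
_VISC_H1[3, 0] = -2.89555e-1
_VISC_H1[0, 1] = 2.22531e-1
_VISC_H1[1, 1] = 9.99115e-1
_VISC_H1[2, 1] = 1.88797
_VISC_H1[3, 1] = 1.26613
_VISC_H1[5, 1] = 1.20573e-1
_VISC_H1[0, 2] = -2.81378e-1
_VISC_H1[1, 2] = -9.06851e-1
_VISC_H1[2, 2] = -7.72479e-1
_VISC_H1[3, 2] = -4.89837e-1
_VISC_H1[4, 2] = -2.57040e-1
_VISC_H1[0, 3] = 1.61913e-1
_VISC_H1[1, 3] = 2.57399e-1
_VISC_H1[0, 4] = -3.25372e-2
_VISC_H1[3, 4] = 6.98452e-2
_VISC_H1[4, 5] = 8.72102e-3
_VISC_H1[3, 6] = -4.35673e-3
_VISC_H1[5, 6] = -5.93264e-4


def water_viscosity(temperature: float) -> float:
    """Dynamic viscosity of liquid water at 0.1 MPa (Pa·s).

    IAPWS 2008 correlation (dilute-gas and residual terms; the critical
    enhancement is negligible at ambient pressure), evaluated at the
    atmospheric-pressure liquid density.  Returns 1.0016 mPa·s at 20 degC
    and 0.31418 mPa·s at 90 degC.

    Raises ``ValueError`` outside 263.15-373.15 K, the liquid (including
    modestly supercooled) range the fit is trusted over here.
    """
    if not 263.15 <= temperature <= 373.15:
        raise ValueError(
            f"water_viscosity valid for 263.15-373.15 K, got {temperature}")
    t_bar = temperature / _VISC_T_STAR
    rho_bar = water_density(temperature) / _VISC_RHO_STAR
    mu0 = 100.0 * math.sqrt(t_bar) / sum(
        h / t_bar**i for i, h in enumerate(_VISC_H0))
    tpow = (1.0 / t_bar - 1.0) ** np.arange(6)
    rpow = (rho_bar - 1.0) ** np.arange(7)
    mu1 = math.exp(rho_bar * float(tpow @ _VISC_H1 @ rpow))
    return mu0 * mu1 * 1e-6


def water(temperature: float = 293.15) -> FluidMedium:
    """Liquid water at the given temperature, with IAPWS viscosity and
    atmospheric-pressure density."""
    return FluidMedium(temperature=temperature,
                       viscosity=water_viscosity(temperature),
                       density=water_density(temperature))


# ---------------------------------------------------------------------------
# Material and environment libraries
# ---------------------------------------------------------------------------

class MaterialLibrary:
    """Density library of materials relevant to in-liquid life detection.

    Maps material name -> density (kg/m^3), with a ``kind`` tag
    (biological / mineral / polymer / fluid) used as ground truth in
    classification sweeps.  The packaged table lists typical aquatic
    cells, buoyant gas-vesicle clusters, reference polymer beads and the
    light end of the mineral spectrum; the density of water at 20 degC
    (998 kg/m^3) is the reference for every tabulated density contrast.
    """

    #: reference fluid density (kg/m^3) for the tabulated contrasts
    WATER_DENSITY = 998.0

    def __init__(self, table: pd.DataFrame):
        required = {"material", "density_kg_m3", "delta_rho_kg_m3", "kind"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"material table missing columns: {sorted(missing)}")
        self._table = table.reset_index(drop=True)
        self._by_name: Mapping[str, pd.Series] = {
            row.material: row for row in table.itertuples()}

    @classmethod
    def default(cls) -> "MaterialLibrary":
        with resources.files("passivemotion.data").joinpath(
                "materials.csv").open("r", encoding="utf-8") as fh:
            return cls(pd.read_csv(fh))

    @property
    def table(self) -> pd.DataFrame:
        return self._table.copy()

    @property
    def names(self) -> list[str]:
        return list(self._table["material"])

    def density(self, material: str) -> float:
        try:
            return float(self._by_name[material].density_kg_m3)
        except KeyError:
            raise KeyError(
                f"unknown material {material!r}; known: {self.names}") from None

    def delta_rho(self, material: str) -> float:
        """Tabulated density contrast against 20 degC water (kg/m^3)."""
        try:
            return float(self._by_name[material].delta_rho_kg_m3)
        except KeyError:
            raise KeyError(
                f"unknown material {material!r}; known: {self.names}") from None

    def kind(self, material: str) -> str:
        try:
            return str(self._by_name[material].kind)
        except KeyError:
            raise KeyError(
                f"unknown material {material!r}; known: {self.names}") from None

    def particle(self, material: str, radius: float) -> ParticleSpec:
        return ParticleSpec(radius=radius, density=self.density(material),
                            label=material)


def load_environments(fluid: FluidMedium | None = None
                      ) -> dict[str, MissionEnvironment]:
    """Packaged gravity environments (Earth, Mars, Europa, Enceladus),
    each paired with `fluid` (default: water at 20 degC)."""
    if fluid is None:
        fluid = water(293.15)
    with resources.files("passivemotion.data").joinpath(
            "environments.csv").open("r", encoding="utf-8") as fh:
        table = pd.read_csv(fh)
    return {str(r.name): MissionEnvironment(str(r.name), float(r.gravity_m_s2), fluid)
            for r in table.itertuples(index=False)}


# ---------------------------------------------------------------------------
# Forward formulas
# ---------------------------------------------------------------------------

def diffusion_coefficient(particle_radius: float, fluid: FluidMedium) -> float:
    """Einstein–Stokes diffusivity D = k_B T / (6 pi eta r) (m^2/s)."""
    if particle_radius <= 0:
        raise ValueError(f"radius must be > 0 m, got {particle_radius}")
    return K_B * fluid.temperature / (6.0 * math.pi * fluid.viscosity
                                      * particle_radius)


def radius_from_diffusivity(D: float, fluid: FluidMedium) -> float:
    """Hydrodynamic radius from a measured diffusivity (exact inverse of
    :func:`diffusion_coefficient`)."""
    if D <= 0:
        raise ValueError(f"diffusivity must be > 0 m^2/s, got {D}")
    return K_B * fluid.temperature / (6.0 * math.pi * fluid.viscosity * D)


def brownian_time(rms_distance: float, D: float, dimensions: int = 1) -> float:
    """Time for Brownian motion to cover an RMS distance (s).

    ``tau_B = x^2 / (2D)`` in one dimension, ``(x^2 + y^2) / (4D)`` in
    two (``rms_distance`` is then the combined in-plane RMS distance).
    """
    if rms_distance <= 0:
        raise ValueError(f"rms_distance must be > 0 m, got {rms_distance}")
    if D <= 0:
        raise ValueError(f"diffusivity must be > 0 m^2/s, got {D}")
    if dimensions not in (1, 2):
        raise ValueError(f"dimensions must be 1 or 2, got {dimensions}")
    return rms_distance**2 / (2.0 * dimensions * D)


def stokes_velocity(particle: ParticleSpec, env: MissionEnvironment) -> float:
    """Stokes terminal velocity v = 2 (rho_p - rho_f) g r^2 / (9 eta)
    (m/s, signed; positive = sinking)."""
    fluid = env.fluid
    return (2.0 * (particle.density - fluid.density) * env.gravity
            * particle.radius**2 / (9.0 * fluid.viscosity))


def density_diff_from_velocity(v: float, radius: float,
                               env: MissionEnvironment) -> float:
    """Particle–fluid density difference from an axial velocity (kg/m^3);
    exact inverse of :func:`stokes_velocity` at fixed radius."""
    if radius <= 0:
        raise ValueError(f"radius must be > 0 m, got {radius}")
    return 9.0 * env.fluid.viscosity * v / (2.0 * env.gravity * radius**2)


def gravity_time(distance: float, particle: ParticleSpec,
                 env: MissionEnvironment) -> float:
    """Time to sink/rise through `distance` at the Stokes velocity (s).

    Neutral buoyancy returns ``inf`` (the particle never traverses the
    distance by gravity alone) rather than raising, so density sweeps
    that cross the fluid density stay total.
    """
    if distance <= 0:
        raise ValueError(f"distance must be > 0 m, got {distance}")
    v = abs(stokes_velocity(particle, env))
    if v == 0.0:
        return math.inf
    return distance / v


def strouhal(particle: ParticleSpec, env: MissionEnvironment) -> float:
    """Particle Strouhal number Sr_p = 3 k_B T / (4 pi |drho| g r^4).

    The ratio of the gravitational transit time over one particle radius
    to the Brownian time over the same distance.  Independent of the
    fluid viscosity (it cancels between the two timescales) and linear in
    temperature.  Neutral buoyancy returns ``inf``.
    """
    drho = abs(particle.density - env.fluid.density)
    if drho == 0.0:
        return math.inf
    return (3.0 * K_B * env.fluid.temperature
            / (4.0 * math.pi * drho * env.gravity * particle.radius**4))


def motion_regime(sr: float, gravity_below: float = 0.1,
                  brownian_above: float = 10.0) -> str:
    """Label the motion regime from a Strouhal number.

    Gravity and diffusion matter equally near ``Sr_p ~ 1``; a decade of
    margin on either side marks clearly gravity- or Brownian-dominated
    motion.  Thresholds are configurable.
    """
    if sr < 0:
        raise ValueError(f"Strouhal number must be >= 0, got {sr}")
    if sr < gravity_below:
        return "gravity"
    if sr > brownian_above:
        return "brownian"
    return "mixed"


def required_observation_time(delta_rho: float, radius: float,
                              axial_resolution: float,
                              env: MissionEnvironment) -> float:
    """Observation time needed for gravitational drift to traverse one
    axial resolution element (s); ``inf`` for neutral buoyancy.

    This is the planning-mode question: how long must a recording be
    before a density contrast `delta_rho` at particle radius `radius`
    produces axial motion resolvable by an instrument with the given
    axial resolution?  Scales as 1/g across gravity environments.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0 m, got {radius}")
    if axial_resolution <= 0:
        raise ValueError(
            f"axial_resolution must be > 0 m, got {axial_resolution}")
    if delta_rho == 0.0:
        return math.inf
    v = abs(2.0 * delta_rho * env.gravity * radius**2
            / (9.0 * env.fluid.viscosity))
    return axial_resolution / v


def strouhal_grid(radii: Sequence[float], densities: Sequence[float],
                  env: MissionEnvironment) -> pd.DataFrame:
    """log10 Strouhal number over a radius x density grid.

    Returns a DataFrame indexed by radius (m) with one column per
    particle density (kg/m^3); cells where the density equals the fluid
    density are ``inf``.  Write with ``DataFrame.to_csv`` for plotting.
    """
    radii = list(radii)
    densities = list(densities)
    if not radii or not densities:
        raise ValueError("radius and density grids must be non-empty")
    out = np.empty((len(radii), len(densities)))
    for i, r in enumerate(radii):
        for j, rho in enumerate(densities):
            sr = strouhal(ParticleSpec(radius=r, density=rho), env)
            out[i, j] = math.inf if math.isinf(sr) else math.log10(sr)
    return pd.DataFrame(out, index=pd.Index(radii, name="radius_m"),
                        columns=pd.Index(densities, name="density_kg_m3"))
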