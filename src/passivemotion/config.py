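"""Flat pipeline configuration, round-trippable through YAML.

One file holds every stage default — fluid temperature, gravity
environment, population, recording geometry, linking, estimation and
classification parameters, and the global seed.  User-facing lengths are
micrometres (the ``_um`` suffix); the library converts to SI at the
boundary.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .classify import DensityThresholds
from .physics import (FluidMedium, MissionEnvironment, load_environments,
                      water)
from .synthetic import (ClusterSize, FixedRadius, LognormalSize,
                        PopulationSpec, RecordingSpec)

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # fluid / environment
    temperature_k: float = 293.15
    environment: str = "Earth"
    # population
    material: str = "Bacterial Cell"
    n_particles: int = 50
    size_model: str = "fixed"          # fixed | lognormal | cluster
    radius_um: float = 0.5
    lognormal_sigma: float = 0.2
    monomer_diameter_um: float = 0.8
    max_multiplicity: int = 4
    # recording
    frame_rate: float = 15.0
    duration_s: float = 30.0
    field_x_um: float = 356.0
    field_y_um: float = 365.0
    chamber_depth_um: float = 1000.0
    sigma_xy_um: float = 0.2
    sigma_z_um: float = 1.0
    drift_x_um_s: float = 0.0
    drift_y_um_s: float = 0.0
    boundary: str = "absorb"           # absorb | reflect | none
    # tracking
    max_disp_um: float = 5.0
    gap_max: int = 2
    threshold: str = "otsu"
    # estimation
    dims: int = 2
    max_lag: int = 3
    radius_source: str = "diffusivity"  # diffusivity | fixed
    outlier_quantity: str = "D"
    outlier_cutoff_um2_s: float = 1.20
    # classification
    cell_below_kg_m3: float = 1300.0
    mineral_above_kg_m3: float = 1500.0
    # reproducibility
    seed: int = 0

    # -- serialization ----------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"{path}: unknown config keys {sorted(unknown)}; "
                f"known keys: {sorted(known)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True),
            encoding="utf-8")

    # -- materialized objects ---------------------------------------------

    def fluid(self) -> FluidMedium:
        return water(self.temperature_k)

    def mission_environment(self) -> MissionEnvironment:
        envs = load_environments(self.fluid())
        try:
            return envs[self.environment]
        except KeyError:
            raise ValueError(
                f"unknown environment {self.environment!r}; "
                f"known: {sorted(envs)}") from None

    def recording_spec(self) -> RecordingSpec:
        return RecordingSpec(
            frame_rate=self.frame_rate, duration=self.duration_s,
            field_xy=(self.field_x_um * 1e-6, self.field_y_um * 1e-6),
            chamber_depth=self.chamber_depth_um * 1e-6,
            sigma_xy=self.sigma_xy_um * 1e-6, sigma_z=self.sigma_z_um * 1e-6,
            drift_xy=(self.drift_x_um_s * 1e-6, self.drift_y_um_s * 1e-6),
            seed=self.seed)

    def population_spec(self) -> PopulationSpec:
        if self.size_model == "fixed":
            model = FixedRadius(self.radius_um * 1e-6)
        elif self.size_model == "lognormal":
            model = LognormalSize(self.radius_um * 1e-6, self.lognormal_sigma)
        elif self.size_model == "cluster":
            model = ClusterSize(self.monomer_diameter_um * 1e-6,
                                self.max_multiplicity)
        else:
            raise ValueError(f"unknown size_model {self.size_model!r}")
        return PopulationSpec(material=self.material,
                              n_particles=self.n_particles,
                              size_model=model,
                              env=self.mission_environment())

    def density_thresholds(self) -> DensityThresholds:
        return DensityThresholds(cell_below=self.cell_below_kg_m3,
                                 mineral_above=self.mineral_above_kg_m3)
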