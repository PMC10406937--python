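"""Run configuration: YAML-backed, schema-validated (unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .contact import ProbeParameters, TissueMechanics
from .errors import ConfigurationError
from .synthetic import DEFAULT_TIMEPOINTS, GroundTruth, TimeCourseSpec

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProbeConfig(_Strict):
    """Spherical probe: 10 um bead (R = 5 um) on a 0.01 N/m cantilever."""

    R_um: float = 5.0
    k_N_per_m: float = 0.01

    def to_probe(self) -> ProbeParameters:
        return ProbeParameters(tip_radius=self.R_um * 1e-6, spring_constant=self.k_N_per_m)


class FitConfig(_Strict):
    model: Literal["hertz", "adhesive"] = "hertz"
    poisson: float = 0.5
    baseline_fraction: float = Field(0.25, gt=0.0, lt=1.0)
    min_converged: float = Field(0.9, ge=0.0, le=1.0)


class GridConfig(_Strict):
    """One simulated measurement grid (a condition x timepoint cell)."""

    youngs_modulus_Pa: float = 330.0
    adhesion_energy_uJ_m2: float = 0.0
    poisson: float = 0.5
    n_curves: int = Field(60, ge=1)
    noise_sigma_pN: float = Field(5.0, ge=0.0)
    contact_point_um: float = 2.0
    baseline_tilt_pN_per_um: float = 0.0
    setpoint_pN: float = 700.0
    rate_um_per_s: float = 2.0
    condition: str = "300mOsm"
    animal: str = "a1"
    time_h: float = 0.5

    def to_truth(self, seed: int) -> GroundTruth:
        tissue = TissueMechanics(
            youngs_modulus=self.youngs_modulus_Pa,
            poisson=self.poisson,
            adhesion_energy=self.adhesion_energy_uJ_m2 * 1e-6,
        )
        return GroundTruth(
            tissue=tissue,
            contact_point=self.contact_point_um * 1e-6,
            baseline_tilt=self.baseline_tilt_pN_per_um * 1e-12 / 1e-6,
            noise_sigma=self.noise_sigma_pN * 1e-12,
            seed=seed,
        )


class TimecourseSimConfig(_Strict):
    """Exponential-plateau time course for one condition and metric."""

    metric: Literal["modulus", "hydration", "volume"] = "modulus"
    condition: str = "300mOsm"
    start_value: float = 330.0
    plateau_value: float = 122.0
    plateau_time_h: float = 2.0
    timepoints: list[float] = Field(default_factory=lambda: list(DEFAULT_TIMEPOINTS))
    animal_cv: float = Field(0.30, ge=0.0)
    n_animals: int | None = None

    def to_spec(self) -> TimeCourseSpec:
        return TimeCourseSpec(
            start_value=self.start_value,
            plateau_value=self.plateau_value,
            plateau_time_h=self.plateau_time_h,
            timepoints=tuple(self.timepoints),
            animal_cv=self.animal_cv,
            condition=self.condition,
        )


class SimulateConfig(_Strict):
    seed: int = 0
    grids: list[GridConfig] = Field(default_factory=lambda: [GridConfig()])
    timecourses: list[TimecourseSimConfig] = Field(default_factory=list)
    wet_mass_mg: float = 100.0  # nominal pooled wet mass for mass records
    slice_images: bool = False  # also render volume time courses as PNG series


class RunConfig(_Strict):
    probe: ProbeConfig = Field(default_factory=ProbeConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration (defaults when ``path`` is None)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        offenders = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigurationError(f"invalid configuration: {offenders}") from exc
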