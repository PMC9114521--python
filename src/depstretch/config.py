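"""Run configuration: schema-validated YAML/JSON with explicit units.

A run configuration collects everything a reproducible run needs:
dielectric parameter sets, electrical drive, device geometry, controller
settings, population models for the simulator, analysis options and the
RNG seed.  Unknown keys are rejected (typos must not silently become
defaults) and unit-carrying strings are converted on load.

Conductivity accepts either a number in S/m or a string with one of the
units S/m, mS/m, uS/cm (μS/cm) — buffer conductivities are commonly
quoted in μS/cm (1 μS/cm = 1e-4 S/m).
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .hydraulics import UL_PER_H, UL_PER_MIN

__all__ = [
    "RunConfig",
    "load_config",
    "parse_conductivity",
    "parse_flow",
    "config_hash",
]

_COND_UNITS = {
    "s/m": 1.0,
    "ms/m": 1e-3,
    "us/cm": 1e-4,
    "μs/cm": 1e-4,
    "µs/cm": 1e-4,
}

_FLOW_UNITS = {
    "m3/s": 1.0,
    "ul/h": UL_PER_H,
    "μl/h": UL_PER_H,
    "µl/h": UL_PER_H,
    "ul/min": UL_PER_MIN,
    "μl/min": UL_PER_MIN,
    "µl/min": UL_PER_MIN,
}


def _parse_quantity(value, units: dict[str, float], what: str) -> float:
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*([^\s]+)\s*", str(value))
    if not m:
        raise ValueError(f"cannot parse {what} {value!r}")
    num, unit = m.groups()
    key = unit.lower()
    if key not in units:
        raise ValueError(
            f"unknown {what} unit {unit!r}; accepted: {sorted(units)}"
        )
    return float(num) * units[key]


def parse_conductivity(value) -> float:
    """Conductivity to S/m; numbers pass through, strings carry units."""
    return _parse_quantity(value, _COND_UNITS, "conductivity")


def parse_flow(value) -> float:
    """Volumetric flow to m^3/s; numbers pass through (already m^3/s)."""
    return _parse_quantity(value, _FLOW_UNITS, "flow")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DielectricSpec(_Strict):
    """One dielectric body; ``sigma`` in S/m (or unit string), radius μm."""

    eps_rel: float = Field(gt=0)
    sigma: float = Field(ge=0)
    radius_um: float | None = Field(default=None, gt=0)

    @field_validator("sigma", mode="before")
    @classmethod
    def _sigma_units(cls, v):
        return parse_conductivity(v)


class ElectricalSpec(_Strict):
    voltage_vpp: float = Field(default=10.0, gt=0)
    frequency_hz: float = Field(default=12e6, gt=0)


class DeviceSpec(_Strict):
    """Trap-array geometry; see hydraulics.DeviceGeometry (lengths μm)."""

    main_width: float = Field(default=100.0, gt=0)
    bypass_width: float = Field(default=100.0, gt=0)
    height: float = Field(default=25.0, gt=0)
    pitch: float = Field(default=100.0, gt=0)
    n_ports_per_side: int = Field(default=10, ge=1)
    port_narrow_width: float = Field(default=6.0, gt=0)
    port_narrow_length: float = Field(default=10.0, gt=0)
    port_wide_width: float = Field(default=18.0, gt=0)
    port_wide_length: float = Field(default=10.0, gt=0)
    viscosity: float = Field(default=1.0e-3, gt=0)


class FieldSpec(_Strict):
    """Facing-tips demo electrode geometry for the field solver."""

    gap_um: float = Field(default=18.0, gt=0)
    domain_um: float = Field(default=60.0, gt=0)
    spacing_um: float = Field(default=0.5, gt=0)


class ControllerSpec(_Strict):
    capture_count_threshold: int = Field(default=10, ge=1)
    stretch_duration_s: float = Field(default=10.0, gt=0)
    voltage_vpp: float = Field(default=10.0, gt=0)
    frequency_hz: float = Field(default=12e6, gt=0)
    capture_flow_ul_h: float = Field(default=3.0, gt=0)
    release_flow_ul_min: float = Field(default=150.0, gt=0)
    frame_rate_fps: float = Field(default=50.0, gt=0)
    release_count_target: int = Field(default=0, ge=0)
    release_efficiency: float = Field(default=1.0, ge=0, le=1)
    max_capture_attempts: int = Field(default=25, ge=1)


class PopulationSpec(_Strict):
    label: str = "normal"
    mean_strain: float = Field(default=0.0864, gt=0)
    cv_strain: float = Field(default=0.6, ge=0)
    length_mean_um: float = Field(default=15.0, gt=0)
    cv_length: float = Field(default=0.10, ge=0)
    noise_sd_um: float = Field(default=0.02, ge=0)
    p_broken: float = Field(default=0.02, ge=0, le=1)
    tau_s: float = Field(default=2.0, ge=0)


class AnalysisSpec(_Strict):
    stress_mode: str = Field(default="calibration", pattern="^(calibration|physics)$")
    calibration_modulus_pa: float = Field(default=203.7, gt=0)
    calibration_strain: float = Field(default=0.0864, gt=0)
    n_geom: float | None = None
    bin_width: float = Field(default=0.03, gt=0)
    bin_upper: float = Field(default=0.09, gt=0)
    broken_fraction: float = Field(default=0.5, gt=0, lt=1)


class RunConfig(_Strict):
    """Top-level run configuration with documented defaults throughout.

    Default dielectric parameters are placeholders for a mammalian cell in
    low-conductivity isotonic buffer (medium eps 78, particle eps 60,
    particle sigma 0.01 S/m, buffer 50 μS/cm), not measured values.
    """

    seed: int = 0
    particle: DielectricSpec = DielectricSpec(eps_rel=60.0, sigma=0.01, radius_um=7.5)
    medium: DielectricSpec = DielectricSpec(eps_rel=78.0, sigma=0.005)
    electrical: ElectricalSpec = ElectricalSpec()
    device: DeviceSpec = DeviceSpec()
    field_solver: FieldSpec = FieldSpec()
    controller: ControllerSpec = ControllerSpec()
    populations: dict[str, PopulationSpec] = Field(
        default_factory=lambda: {
            "normal": PopulationSpec(label="normal", mean_strain=0.0864),
            "treated": PopulationSpec(label="treated", mean_strain=0.1013),
        }
    )
    analysis: AnalysisSpec = AnalysisSpec()


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Defaults fill every omitted section; unknown keys raise a validation
    error naming the key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 of the fully-resolved configuration."""
    canon = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()
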