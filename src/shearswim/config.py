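"""Run configuration, canonical fixtures and manifest support.

A :class:`RunConfig` bundles everything a simulation needs: swimmer
morphology and beat, background flow and wall, repulsion parameters and
numerical settings.  Defaults reproduce the virtual promastigote scenario
(body 11 × 3.5 μm, flagellum 13 μm, A = 1.8 μm, λ = 13 μm, f = 28 Hz,
tip-to-base puller beat, γ_d = 1 s⁻¹).  Configurations are flat-ish JSON
with schema validation; unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .bem import WATER_VISCOSITY_25C, FlowModel
from .geometry import SwimmerConfig
from .walls import WallRepulsion

__all__ = ["RunConfig", "load_config", "save_config", "make_fixture", "FIXTURE_NAMES"]


class _SwimmerSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    body_major_axis: float = Field(11.0, gt=0)
    body_minor_axis: float = Field(3.5, gt=0)
    flagellum_length: float = Field(13.0, gt=0)
    flagellum_radius: float = Field(0.25, gt=0)
    beat_amplitude: float = Field(1.8, ge=0)
    beat_wavelength: float = Field(13.0, gt=0)
    beat_frequency: float = Field(28.0, gt=0)
    beat_direction: Literal["puller", "pusher"] = "puller"
    body_scale: float = Field(1.0, gt=0)

    @field_validator("beat_amplitude")
    @classmethod
    def _amp_lt_length(cls, v, info):
        L = info.data.get("flagellum_length", 13.0)
        if v >= L:
            raise ValueError("beat_amplitude must be smaller than flagellum_length")
        return v


class _FlowSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    gamma_d: float = 1.0
    geometry: Literal["bulk_shear", "wall_shear"] = "bulk_shear"
    viscosity: float = Field(WATER_VISCOSITY_25C, gt=0)
    wall_present: bool = False


class _RepulsionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    strength: float = Field(1250.0, gt=0)
    decay_length: float = Field(0.2, gt=0)
    enabled: bool = False


class _NumericsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dt_beat_fraction: float = Field(0.01, gt=0)  # dt = beat period × fraction
    n_phases: int = Field(20, ge=2)
    refinement: int = 1
    n_theta: int = Field(24, ge=4)
    h_min: float = Field(2.5, gt=0)
    h_max: float = Field(30.0, gt=0)
    n_h: int = Field(16, ge=3)
    seed: int = 0
    newton_tol: float = Field(1e-10, gt=0)


class RunConfig(BaseModel):
    """Validated bundle of swimmer, flow, repulsion and numerics settings."""

    model_config = ConfigDict(extra="forbid")

    swimmer: _SwimmerSection = Field(default_factory=_SwimmerSection)
    flow: _FlowSection = Field(default_factory=_FlowSection)
    repulsion: _RepulsionSection = Field(default_factory=_RepulsionSection)
    numerics: _NumericsSection = Field(default_factory=_NumericsSection)
    output_dir: str = "shearswim_out"

    def swimmer_config(self) -> SwimmerConfig:
        s = self.swimmer
        return SwimmerConfig(
            body_major_axis=s.body_major_axis,
            body_minor_axis=s.body_minor_axis,
            flagellum_length=s.flagellum_length,
            flagellum_radius=s.flagellum_radius,
            beat_amplitude=s.beat_amplitude,
            beat_wavelength=s.beat_wavelength,
            beat_frequency=s.beat_frequency,
            beat_direction=s.beat_direction,
            body_scale=s.body_scale,
        )

    def flow_model(self) -> FlowModel:
        rep = None
        if self.repulsion.enabled:
            rep = WallRepulsion(
                strength=self.repulsion.strength,
                decay_length=self.repulsion.decay_length,
                beat_period=1.0 / self.swimmer.beat_frequency,
                enabled=True,
            )
        return FlowModel(
            gamma_d=self.flow.gamma_d,
            geometry=self.flow.geometry,
            viscosity=self.flow.viscosity,
            wall_present=self.flow.wall_present,
            repulsion=rep,
        )

    @property
    def dt(self) -> float:
        return self.numerics.dt_beat_fraction / self.swimmer.beat_frequency

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration.

    An empty file (or empty object) yields the full default virtual
    promastigote configuration.  Unknown keys raise a descriptive error.
    """
    text = Path(path).read_text().strip()
    data = json.loads(text) if text else {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a JSON object, got {type(data).__name__}")
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg.model_dump(), indent=2, sort_keys=True) + "\n")


FIXTURE_NAMES = ("promastigote", "pusher", "passive_spheroid(r)", "small_body_0.2")

_SPHEROID_RE = re.compile(r"^passive_spheroid\((?P<r>[0-9.]+)\)$")


def make_fixture(name: str) -> RunConfig:
    """Canonical configurations used throughout the test and acceptance suite.

    * ``promastigote`` — the default virtual promastigote (tip-to-base puller);
    * ``pusher`` — identical morphology, reversed beat direction;
    * ``passive_spheroid(r)`` — no beat (A = 0), no flagellum influence beyond
      a hairline tube, body aspect ratio r (minor axis 3.5 μm retained);
    * ``small_body_0.2`` — body length scale reduced by 80%.
    """
    if name == "promastigote":
        return RunConfig()
    if name == "pusher":
        cfg = RunConfig()
        cfg.swimmer.beat_direction = "pusher"
        return cfg
    if name == "small_body_0.2":
        cfg = RunConfig()
        cfg.swimmer.body_scale = 0.2
        return cfg
    m = _SPHEROID_RE.match(name)
    if m:
        r = float(m.group("r"))
        if r < 1.0:
            raise ValueError("passive spheroid aspect ratio must be ≥ 1")
        cfg = RunConfig()
        cfg.swimmer.beat_amplitude = 0.0
        cfg.swimmer.body_major_axis = r * cfg.swimmer.body_minor_axis
        return cfg
    raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")


def write_manifest(cfg: RunConfig, path: str | Path, extra: Optional[dict] = None) -> None:
    """Write a reproducibility manifest (config hash, version, seed)."""
    from . import __version__

    manifest = {
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "seed": cfg.numerics.seed,
        "config": cfg.model_dump(),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
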