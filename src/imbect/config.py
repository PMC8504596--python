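"""Structured run configuration: one YAML file drives every planning stage.

The schema is validated (pydantic) before any stage runs, and every run
writes a manifest recording the configuration hash, package version and the
seed, so a rerun with the same config and seed is reproducible bit for bit
(the core math is deterministic; only fixture jitter, when requested,
consumes the seeded generator).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["RunConfig", "load_config", "write_manifest"]


class BeamConfig(BaseModel):
    energy_mev: float = 16.0
    r90_cm: float = 5.0
    sigma_theta0_rad: float = 0.03
    xray_tail_pct: float = 3.0


class PhantomConfig(BaseModel):
    kind: Literal["water_tank", "wavy_slab"] = "wavy_slab"
    ssd_cm: float = 100.0
    extent_cm: tuple[float, float, float] = (14.0, 14.0, 8.0)
    spacing_cm: tuple[float, float, float] = (0.2, 0.2, 0.2)
    ptv_distal_amplitude_cm: float = 0.5
    ptv_period_cm: float = 8.0
    ptv_distal_depth_cm: float = 3.0
    ptv_proximal_depth_cm: float = 0.4
    ptv_half_width_cm: tuple[float, float] = (3.0, 3.0)


class ApertureConfig(BaseModel):
    width_cm: float = 10.0
    height_cm: float = 10.0


class OperatorStep(BaseModel):
    op: Literal[
        "create", "smooth", "isodose_shift", "specified_shift", "truncate",
        "intensity_modulation",
    ]
    percent: Optional[float] = None
    inner_margin: Optional[float] = None
    exp_mult: Optional[float] = None
    radius_mult: Optional[float] = None
    delta: Optional[float] = None
    margin: Optional[float] = None

    def as_call(self) -> dict:
        params = self.model_dump(exclude_none=True)
        params.pop("op")
        return {"op": self.op, **params}


class ModulationConfig(BaseModel):
    irf_min: float = 0.8
    irf_max: float = 1.0

    @field_validator("irf_min")
    @classmethod
    def _check_min(cls, v):
        if not (0.0 < v <= 1.0):
            raise ValueError("irf_min must lie in (0, 1]")
        return v


class CatalogConfig(BaseModel):
    diameters_cm: Optional[list[float]] = None
    lattice_r_cm: float = 0.6
    plane_cm: float = 93.5


class QAConfig(BaseModel):
    dose_tol_pct: float = 3.0
    dist_tol_cm: float = 0.3
    threshold_pct: float = 10.0
    threshold_mode: Literal["max", "given"] = "max"
    dta_cap_cm: float = 1.0


class RunConfig(BaseModel):
    beam: BeamConfig = Field(default_factory=BeamConfig)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    aperture: ApertureConfig = Field(default_factory=ApertureConfig)
    sequence: list[OperatorStep] = Field(default_factory=list)
    modulation: ModulationConfig = Field(default_factory=ModulationConfig)
    catalog: CatalogConfig = Field(default_factory=CatalogConfig)
    qa: QAConfig = Field(default_factory=QAConfig)
    bolus_density: float = 0.92
    seed: int = 0
    output_dir: str = "imbect-out"

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def write_manifest(config: RunConfig, out_dir: Path, extra: dict | None = None) -> Path:
    from . import __version__

    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "imbect_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
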