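"""JSON configuration loading.

One JSON document describes a whole experiment: fluid constants (SI),
emission parameters (speed in m/s, angles in degrees, diameters in um) and
geometry (in centimetres — the bench is laid out with a ruler; conversion to
SI happens here at the boundary), plus a list of barriers and a seed.
Every block and every field is optional; omitted values take the study
defaults.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

from .physics import FluidEnvironment
from .simulator import Barrier, EmissionModel, ExperimentGeometry

__all__ = ["ExperimentConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """A configuration document is malformed; the message names the field."""


@dataclass(frozen=True)
class ExperimentConfig:
    env: FluidEnvironment
    emission: EmissionModel
    geometry: ExperimentGeometry
    barriers: tuple[Barrier, ...]
    seed: int
    sha256: str  # hash of the normalised document, embedded in outputs

    def seeded(self, seed: Optional[int]) -> "ExperimentConfig":
        """Copy with the seed (and the emission model's seed) overridden."""
        if seed is None:
            return self
        emission = EmissionModel(
            **{**_emission_kwargs(self.emission), "seed": int(seed)}
        )
        return ExperimentConfig(self.env, emission, self.geometry, self.barriers, int(seed), self.sha256)


def _emission_kwargs(m: EmissionModel) -> dict:
    return {
        "speed": m.speed,
        "angle_low": m.angle_low,
        "angle_high": m.angle_high,
        "mean_diameter_um": m.mean_diameter_um,
        "sd_diameter_um": m.sd_diameter_um,
        "min_diameter_um": m.min_diameter_um,
        "diameters_um": m.diameters_um,
        "count": m.count,
        "seed": m.seed,
    }


def _get(block: dict, key: str, default: Any, context: str):
    value = block.get(key, default)
    if value is None and default is not None:
        raise ConfigError(f"config field '{context}.{key}' must not be null")
    return value


def load_config(source: str | Path | dict) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a JSON file, string or dict."""
    if isinstance(source, dict):
        doc = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a JSON object")

    sha = hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()
    try:
        fluid = doc.get("fluid", {})
        env = FluidEnvironment(
            air_viscosity=float(_get(fluid, "air_viscosity_pa_s", 18.73e-6, "fluid")),
            liquid_density=float(_get(fluid, "liquid_density_kg_m3", 995.7, "fluid")),
            gravity=float(_get(fluid, "gravity_m_s2", 9.81, "fluid")),
        )
        seed = int(doc.get("seed", 0))
        em = doc.get("emission", {})
        emission = EmissionModel(
            speed=float(_get(em, "speed_m_s", 3.0, "emission")),
            angle_low=math.radians(float(_get(em, "angle_low_deg", -10.0, "emission"))),
            angle_high=math.radians(float(_get(em, "angle_high_deg", 10.0, "emission"))),
            mean_diameter_um=float(_get(em, "mean_diameter_um", 54.0, "emission")),
            sd_diameter_um=float(_get(em, "sd_diameter_um", 52.3, "emission")),
            min_diameter_um=float(_get(em, "min_diameter_um", 7.0, "emission")),
            diameters_um=em.get("diameters_um"),
            count=int(_get(em, "count", 100_000, "emission")),
            seed=seed,
        )
        geo = doc.get("geometry", {})
        geometry = ExperimentGeometry(
            screen_distance=float(_get(geo, "screen_distance_cm", 19.0, "geometry")) / 100.0,
            nozzle_height=float(_get(geo, "nozzle_height_cm", 10.0, "geometry")) / 100.0,
            screen_y_min=float(_get(geo, "screen_y_min_cm", 0.0, "geometry")) / 100.0,
            screen_y_max=float(_get(geo, "screen_y_max_cm", 20.0, "geometry")) / 100.0,
            roi_half_height=float(_get(geo, "roi_half_height_cm", 2.0, "geometry")) / 100.0,
        )
        barriers = []
        for i, b in enumerate(doc.get("barriers", [])):
            for key in ("distance_from_nozzle_cm", "tunneling_probability", "deceleration_factor"):
                if key not in b:
                    raise ConfigError(f"config field 'barriers[{i}].{key}' is missing")
            barriers.append(
                Barrier(
                    distance_from_nozzle=float(b["distance_from_nozzle_cm"]) / 100.0,
                    tunneling_probability=float(b["tunneling_probability"]),
                    deceleration_factor=float(b["deceleration_factor"]),
                )
            )
    except ConfigError:
        raise
    except (TypeError, ValueError, KeyError) as exc:
        raise ConfigError(f"invalid configuration value: {exc}") from exc

    return ExperimentConfig(
        env=env, emission=emission, geometry=geometry, barriers=tuple(barriers), seed=seed, sha256=sha
    )
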