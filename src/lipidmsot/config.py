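"""Schema-validated pipeline configuration (YAML).

Unknown keys are rejected so typos fail loudly; the simulation seed is
mandatory — every random draw in a run flows from it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    height: int = 400
    width: int = 400
    pixel_pitch: float = 0.1
    skin_row: int = 60
    skin_thickness: float = 1.5
    fat_thickness_range: tuple[float, float] = (5.0, 9.0)
    vein_radius_range: tuple[float, float] = (1.2, 1.8)
    artery_radius_range: tuple[float, float] = (1.1, 1.4)


class KineticsConfig(_Strict):
    baseline: float = 1.0
    amplitude: float = 0.0
    peak_time: float = 180.0
    shape: float = 3.0


class ScheduleConfig(_Strict):
    time_points: Optional[list[float]] = None   # default: 0..360 step 30
    wavelengths: Optional[list[float]] = None   # default: 700..970 step 10


class SimulationConfig(_Strict):
    seed: int
    geometry: GeometryConfig = GeometryConfig()
    kinetics: dict[str, KineticsConfig] = {
        "vein": KineticsConfig(amplitude=0.839, peak_time=187.5),
        "artery": KineticsConfig(amplitude=0.634, peak_time=232.5),
        "muscle": KineticsConfig(amplitude=1.208, peak_time=180.0),
        "fat": KineticsConfig(amplitude=0.328, peak_time=217.5),
    }
    schedule: ScheduleConfig = ScheduleConfig()
    noise_frac: float = 0.02
    psf_fwhm: float = 0.3


class AnalysisConfig(_Strict):
    wavelength: float = 930.0
    use_ground_truth_masks: bool = True
    mask_dir: Optional[str] = None
    profile_lines: list[tuple[tuple[int, int], tuple[int, int]]] = []


class OutputConfig(_Strict):
    directory: str = "results"


class PipelineConfig(_Strict):
    simulation: SimulationConfig
    analysis: AnalysisConfig = AnalysisConfig()
    output: OutputConfig = OutputConfig()


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; errors name the offending key."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        locs = "; ".join(
            "/".join(str(p) for p in err["loc"]) + f": {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"{path}: invalid config ({locs})") from exc
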