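"""Run configuration: YAML-backed, schema-validated, fully serializable.

A run is reproducible from config + seed alone.  Unknown fields are
rejected by name, so typos fail loudly rather than silently falling back
to defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    """Study-design parameters of the simulated experiment."""

    true_fraction_log10: float = -5.2
    sample_dilutions_log10: list[float] = [-2.0, -1.0]
    calibration_dilutions_log10: list[float] = [
        -10.0, -9.0, -8.0, -7.0, -6.0, -5.0, -4.0, -3.0, -2.0]
    n_animals: int = 3
    main: str = "benzaldehyde_d5"
    contaminant: str = "ethyl_acetate"
    reference: str = "ethyl_butyrate"
    gain_spread: float = 0.2
    noise_sd: float | None = None
    channel_offset: float = 0.0


class AnalysisConfig(_Strict):
    """Analysis-stage parameters (windows, thresholds)."""

    window_halfwidth: float = 10.0
    prominence_mult: float = 3.0
    detection_mult: float = 2.0
    saturation_frac: float = 0.95
    alignment_search_window: float = 30.0
    mask_z: float = 3.0


class RunConfig(_Strict):
    """Top-level pipeline configuration."""

    seed: int = 0
    out_dir: str | None = None
    simulate: SimulateConfig = SimulateConfig()
    analysis: AnalysisConfig = AnalysisConfig()


def load_config(path: Path | str) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises
    ------
    ConfigError
        Naming the offending field(s) on schema violations.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>"
            for err in exc.errors())
        raise ConfigError(f"invalid config field(s): {fields}") from exc
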