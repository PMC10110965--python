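"""Validated pipeline configuration.

A YAML (or dict) config is validated against a strict schema: unknown keys
are rejected, constraints are named in error messages, and the fully resolved
config (defaults filled) can be re-emitted and round-tripped.  The SHA-256
hash of the resolved YAML stamps every output for provenance.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "Seeds"]

_SPACES = ("scalp", "seeg", "source", "component", "pooled")


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class Seeds(_Strict):
    simulation: int = 0
    folds: int = 0
    permutations: int = 0


class SimulationConfig(_Strict):
    n_block_pairs: int = Field(7, ge=1)
    images_per_block: int = Field(12, ge=1)
    isi_s: float = Field(2.5, gt=0)
    inter_block_gap_s: float = Field(60.0, ge=0)
    fs_raw: float = Field(512.0, ge=256.0)
    n_scalp: int = Field(32, ge=1)
    n_shafts: int = Field(10, ge=1)
    contacts_per_shaft: int = Field(12, ge=2)
    sphere_radius_mm: float = Field(90.0, gt=0)
    n_sources: int = Field(2, ge=1)
    snr_scalp: float = Field(0.25, gt=0)
    snr_depth: float = Field(2.5, gt=0)
    accuracy: float = Field(0.8953, gt=0, le=1)
    rt_mean_old_s: float = Field(0.7191, gt=0)
    rt_sd_old_s: float = Field(0.1624, gt=0)
    rt_mean_new_s: float = Field(0.7650, gt=0)
    rt_sd_new_s: float = Field(0.1912, gt=0)
    effect_window_s: tuple[float, float] = (0.3, 0.5)
    baseline_amplitude_nAm: float = Field(30.0, gt=0)
    differential_amplitude_nAm: float = Field(20.0, ge=0)


class PreprocessingConfig(_Strict):
    fs: float = Field(256.0, gt=0)
    band_lo_hz: float = Field(0.5, gt=0)
    band_hi_hz: float = Field(45.0, gt=0)
    epoch_tmin_s: float = -0.2
    epoch_tmax_s: float = 1.0
    z_max: float = Field(6.0, gt=0)

    @model_validator(mode="after")
    def _check(self):
        if not self.band_lo_hz < self.band_hi_hz < self.fs / 2:
            raise ValueError("band must satisfy lo < hi < fs/2")
        if not self.epoch_tmin_s < 0 < self.epoch_tmax_s:
            raise ValueError("epoch window must bracket stimulus onset")
        return self


class BeamformerConfig(_Strict):
    grid_spacing_mm: float = Field(5.0, gt=0)
    brain_radius_mm: float = Field(78.0, gt=0)
    shrinkage: float = Field(0.05, ge=0, le=1)


class SobiConfig(_Strict):
    lag_max: int = Field(50, ge=1)
    eps: float = Field(1e-10, ge=0)


class DecodingConfig(_Strict):
    n_folds: int = Field(20, ge=2, description="n_folds must be >= 2")
    l2: float = Field(1.0, ge=0)
    time_window_s: tuple[float, float] | None = None


class InferenceConfig(_Strict):
    forming_p: float = Field(0.05, gt=0, lt=1)
    n_perm: int = Field(1024, ge=64)
    alpha: float = Field(0.05, gt=0, le=1)


class PatternConfig(_Strict):
    bin_s: float = Field(0.2, gt=0)
    statistic: str = "signed-mean"

    @model_validator(mode="after")
    def _check(self):
        if self.statistic not in ("signed-mean", "mean-magnitude"):
            raise ValueError("statistic must be signed-mean or mean-magnitude")
        return self


class PipelineConfig(_Strict):
    seeds: Seeds = Seeds()
    simulation: SimulationConfig = SimulationConfig()
    preprocessing: PreprocessingConfig = PreprocessingConfig()
    beamformer: BeamformerConfig = BeamformerConfig()
    sobi: SobiConfig = SobiConfig()
    decoding: DecodingConfig = DecodingConfig()
    inference: InferenceConfig = InferenceConfig()
    patterns: PatternConfig = PatternConfig()
    spaces: list[str] = ["scalp", "seeg", "source", "pooled"]
    out_dir: str = "vseeg_output"

    @model_validator(mode="after")
    def _check_spaces(self):
        for s in self.spaces:
            if s not in _SPACES and not s.startswith("roi:"):
                raise ValueError(
                    f"space {s!r} not in {_SPACES} and not 'roi:<label>'")
        return self

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def validate_config(source: str | dict | Path | None = None) -> PipelineConfig:
    """Parse and validate a config from YAML text, a file path, or a dict.

    Defaults are filled; unknown keys and constraint violations raise
    :class:`ConfigError` naming the offending key.
    """
    if source is None:
        data = {}
    elif isinstance(source, dict):
        data = source
    else:
        text = str(source)
        if "\n" not in text:
            try:
                if Path(text).is_file():
                    text = Path(text).read_text()
            except OSError:
                pass
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    try:
        return PipelineConfig(**data)
    except ValidationError as err:
        msgs = [f"{'.'.join(str(l) for l in e['loc'])}: {e['msg']}"
                for e in err.errors()]
        raise ConfigError("; ".join(msgs)) from err
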