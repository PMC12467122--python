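"""Pipeline configuration: every tunable of every stage, YAML round-trip.

Unknown keys are rejected so that typos in config files fail loudly.
"""

from __future__ import annotations

import os

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration content."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class PreprocessConfig(_Strict):
    window: str = "hann"
    clutter_cutoff_hz: float = 0.1
    use_clutter_filter: bool = True
    search_range_m: tuple[float, float] = (0.2, 1.5)
    hr_band_hz: tuple[float, float] = (0.5, 3.0)
    use_hilbert_kalman: bool = True
    hk_delta: float = 1.5


class Stage1Config(_Strict):
    wavelet: str = "db4"
    levels: int = 3
    ar_order: int = 12
    psd_points: int = 512
    prominence_frac: float = 0.05
    harmonic_ratio: tuple[float, float] = (1.8, 2.2)
    amp_ratio_mean: float = 1.25
    harmonic_tol: float = 0.10
    jump_limit_bpm: float = 15.0
    band_hz: tuple[float, float] = (0.5, 2.5)
    # consecutive rejected chunks before the history is cleared (re-acquisition)
    reacquire_after: int = 4


class Stage2Config(_Strict):
    n_freqs: int = 200
    f_lo_hz: float = 0.5
    f_hi_hz: float = 2.5
    half_width_bpm: float = 12.5
    prominence_frac: float = 0.05
    # average the two window peaks only when comparable (energy ratio below
    # this); a dominant line is otherwise taken alone.  None: always average.
    pair_max_ratio: float | None = 4.0
    max_iter: int = 500
    tol: float = 1e-6
    prune_alpha: float = 1e9


class FuseConfig(_Strict):
    Q: float = 0.5
    R0: float = 25.0
    R1: float = 9.0
    # with the state initialised from the median of the first coarse
    # estimates, P0 of the order of one measurement variance is appropriate
    P0: float = 25.0
    r1_fallback_inflation: float = 4.0
    # Huber clip (in innovation sigmas) bounding the influence of outlier
    # chunk estimates on the fused trace; None disables
    huber_delta: float | None = 2.0


class EvaluateConfig(_Strict):
    sd_scope: str = "per-recording"   # or "pooled"


class PipelineConfig(_Strict):
    version: str = "1"
    seed: int = 0
    chunk_len_s: float = 5.0
    preprocess: PreprocessConfig = PreprocessConfig()
    stage1: Stage1Config = Stage1Config()
    stage2: Stage2Config = Stage2Config()
    fuse: FuseConfig = FuseConfig()
    evaluate: EvaluateConfig = EvaluateConfig()

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        try:
            return cls.model_validate(raw)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")
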