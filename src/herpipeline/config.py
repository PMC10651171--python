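"""YAML configuration mirroring the pipeline's tunables.

One flat file drives a full run: simulation parameters (nested under
``simulation``) plus the preprocessing, heartbeat, epoching and
statistics knobs.  Anything omitted keeps its library default, so a
config only needs the values a study actually changes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .sim import EffectSpec, SimConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Every tunable the stages accept, with library defaults."""

    simulation: SimConfig = field(default_factory=SimConfig)
    # preprocessing
    bandpass_low_hz: float = 1.0
    bandpass_high_hz: float = 25.0
    filter_design: str = "butter"          # or "fir"
    channel_reject_z: float = 3.0
    neighbor_max_distance_cm: float = 4.0
    corr_threshold: float = 0.80
    corr_weighting: str = "inverse"        # or "inverse_sq"
    ica_method: str = "fastica"            # or "infomax"
    analysis_subset: list[str] | None = None  # 64-channel montage names
    # heartbeats
    detect_window_ms: float = 600.0
    detect_refractory_ms: float = 300.0
    # epoching
    amp_reject_uv: float = 300.0
    ibi_floor_ms: float = 500.0
    stim_guard_ms: float = 20.0
    baseline_correct: bool = False
    pooling: str = "epochs"                # or "conditions"
    # statistics
    cluster_alpha: float = 0.05
    min_cluster_channels: int = 4
    n_partitions: int = 10_000
    n_surrogates: int = 100
    surrogate_partitions: int = 1_000
    bonferroni_family: int = 8
    # classification
    n_folds: int = 5
    seed: int = 0


_EFFECT_FIELDS = ("erp_local", "erp_global", "her_local", "her_global")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim_raw = raw.pop("simulation", {}) or {}
    for key in _EFFECT_FIELDS:
        if key in sim_raw and isinstance(sim_raw[key], dict):
            sim_raw[key] = EffectSpec(**sim_raw[key])
    known = {f.name for f in fields(PipelineConfig)} - {"simulation"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return PipelineConfig(simulation=SimConfig(**sim_raw), **raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    data = asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
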