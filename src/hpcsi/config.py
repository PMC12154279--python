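"""Pipeline configuration: nested dataclasses mirrored by a YAML file.

Unknown keys are rejected so typos fail loudly; a config round-trips
losslessly through the YAML serializer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .recon import ReconConfig

__all__ = [
    "CohortConfig",
    "SimConfig",
    "QuantifyConfig",
    "StatsConfig",
    "PipelineConfig",
    "load_config",
    "dump_config",
]


@dataclass(frozen=True)
class CohortConfig:
    n_naive: int = 4
    n_injury: int = 5
    target_snr: float = 30.0
    rate_jitter_sd: float = 0.1
    lesion_kpb_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.n_naive < 1 or self.n_injury < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.target_snr <= 0:
            raise ValueError("target_snr must be positive")
        if not 0 <= self.rate_jitter_sd < 1:
            raise ValueError("rate_jitter_sd must be in [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    matrix: int = 16
    fov_mm: float = 60.0
    n_spectral: int = 256
    spectral_bw_hz: float = 5000.0
    slice_mm: float = 8.0
    total_time_s: float = 16.0
    n_missing: int = 4
    f0_mhz: float = 32.13
    start_time_s: float = 30.0
    hydrate_fraction: float = 0.0


@dataclass(frozen=True)
class QuantifyConfig:
    window_hz: float = 44.0
    search_hz: float = 60.0
    use_fits: bool = True


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)


def _build(cls, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or cls.__name__} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} in section {path or 'root'}"
        )
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        nested = {
            "cohort": CohortConfig,
            "sim": SimConfig,
            "recon": ReconConfig,
            "quantify": QuantifyConfig,
            "stats": StatsConfig,
        }
        if name in nested and cls is PipelineConfig:
            kwargs[name] = _build(nested[name], value, path=f"{path}{name}.")
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, data: dict | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file or a dict."""
    if data is None:
        if path is None:
            return PipelineConfig()
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    return _build(PipelineConfig, data)


def dump_config(cfg: PipelineConfig, path: str | Path | None = None) -> str:
    """Serialize a config to YAML (round-trips through :func:`load_config`)."""
    text = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
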