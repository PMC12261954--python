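"""Structured-text pipeline configuration.

Groups the protocol, preprocessing and analysis defaults in one
dataclass with YAML round-tripping, so a whole analysis run can be
described by a single text file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # acquisition
    sample_rate: float = 512.0
    n_channels: int = 128
    frame_rate: float = 75.0
    # stimulus geometry
    n_wedges: int = 16
    inner_ecc: float = 2.75
    outer_ecc: float = 7.25
    # protocols
    transient_trials_per_wedge: int = 200
    transient_flash_ms: float = 50.0
    transient_soa_ms: float = 550.0
    mseq_order: int = 12
    mseq_keep_every: int = 4
    mseq_stream_lag: int = 255
    ssvep_freqs: tuple[float, float] = (7.5, 18.75)
    ssvep_epochs: int = 6
    ssvep_epoch_s: float = 5.0
    raster_full_delay_ms: float = 11.5
    # preprocessing
    lowpass_taps: int = 77
    mains_hz: float = 50.0
    detrend_segment_s: dict = field(
        default_factory=lambda: {"transient": 4.0, "ssvep": 5.0, "mfvep": 0.5}
    )
    reject_window_ms: tuple[float, float] = (-50.0, 200.0)
    # derivation
    epoch_window_ms: tuple[float, float] = (-100.0, 400.0)
    c1_window_ms: tuple[float, float] = (70.0, 80.0)
    ssvep_analysis_epoch_s: float = 4.0
    ssvep_discard_s: float = 0.5
    # statistics
    n_permutations: int = 1_000_000
    lag_range_ms: float = 66.0
    timecourse_window_ms: float = 10.0
    timecourse_step_ms: float = 5.0
    n_bootstrap: int = 1000


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    for key, val in raw.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown configuration key {key!r}")
        default = getattr(cfg, key)
        if isinstance(default, tuple) and isinstance(val, list):
            val = tuple(val)
        setattr(cfg, key, val)
    return cfg
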