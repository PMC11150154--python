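"""Configuration dataclasses for the simulator, detector, learner, and matcher.

Every tunable the pipeline exposes lives here with its default.  Defaults for
the simulator are calibrated to the printed severity statistics of nocturnal
sec-surges in suspected-OSA patients (≈19.5 SA-related and 16.4 non-SA
surges per night, amplitude ≈ 26.0 ± 4.3 mmHg, peak ≈ 148.2 mmHg);
detector window/stability defaults are engineering choices sized to a surge
lasting several tens of seconds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

__all__ = [
    "DetectorConfig",
    "LearnerConfig",
    "MatchConfig",
    "SimConfig",
    "PipelineConfig",
    "load_config",
    "save_config",
]


@dataclass
class DetectorConfig:
    """Candidate-extraction parameters.

    ``decay_fraction`` is the end-point rule: the surge ends at the first
    beat whose SBP has fallen by this fraction of the amplitude below the
    peak.  All durations are in seconds, pressures in mmHg.
    """

    window_s: float = 60.0           # sliding-window width for local maxima
    min_amplitude_mmHg: float = 15.0  # minimum candidate amplitude
    stability_beats: int = 10        # trailing window length for start search
    stability_range_mmHg: float = 5.0
    max_lookback_s: float = 120.0    # how far back a start may be
    decay_fraction: float = 0.75     # end point: 75% amplitude decay
    max_recovery_s: float = 180.0    # how far forward an end may be
    gap_split_s: float = 10.0        # gaps longer than this split the night

    def validate(self) -> None:
        if not 0.0 < self.decay_fraction < 1.0:
            raise ValueError("decay_fraction must be in (0, 1)")
        for name in ("window_s", "max_lookback_s", "max_recovery_s",
                     "gap_split_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_amplitude_mmHg < 0:
            raise ValueError("min_amplitude_mmHg must be >= 0")
        if self.stability_beats < 2:
            raise ValueError("stability_beats must be >= 2")
        if self.stability_range_mmHg <= 0:
            raise ValueError("stability_range_mmHg must be > 0")


@dataclass
class LearnerConfig:
    """Rule-learning parameters.

    Thresholds are searched over per-feature quantile grids
    (``grid_quantile_range`` split into ``grid_steps`` levels) plus a
    fully-permissive sentinel that lets the joint search deactivate a
    condition.  Groups whose best single-feature F-measure falls below
    ``min_single_feature_f`` are dropped.
    """

    grid_quantile_range: Tuple[float, float] = (0.05, 0.95)
    grid_steps: int = 19
    min_single_feature_f: float = 0.5
    max_conditions: int = 6
    max_grid_combinations: int = 10_000_000
    tie_break: str = "higher_recall_then_lower_threshold"

    def validate(self) -> None:
        lo, hi = self.grid_quantile_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("grid_quantile_range must satisfy 0 <= lo < hi <= 1")
        if self.grid_steps < 1:
            raise ValueError("grid_steps must be >= 1")
        if not 0.0 <= self.min_single_feature_f <= 1.0:
            raise ValueError("min_single_feature_f must be in [0, 1]")
        if not 1 <= self.max_conditions <= 6:
            raise ValueError("max_conditions must be in [1, 6]")


@dataclass
class MatchConfig:
    """Detection-to-label matching: a detected peak matches a label if it
    falls inside the label interval widened by ``tolerance_s`` on each side."""

    tolerance_s: float = 10.0

    def validate(self) -> None:
        if self.tolerance_s < 0:
            raise ValueError("tolerance_s must be >= 0")


@dataclass
class SimConfig:
    """Synthetic overnight-recording generator parameters.

    A night is a jittered ~1 Hz beat train carrying a slowly drifting
    baseline, planted raised-cosine surges (SA-related surges preceded by a
    PSG event), sub-threshold "confuser" BPV bumps, beat noise, and flagged
    motion-artifact spikes.
    """

    duration_s: float = 25200.0               # 7 h
    mean_beat_interval_s: float = 1.0
    beat_interval_jitter_sd_s: float = 0.05
    baseline_sbp_mmHg: float = 122.2          # so mean peak ≈ 122.2 + 26.0
    drift_amplitude_mmHg: float = 5.0
    drift_period_s: float = 5400.0
    beat_noise_sd_mmHg: float = 2.0
    sa_surge_rate_per_night: float = 19.5
    nonsa_surge_rate_per_night: float = 16.4
    surge_amplitude_mean_mmHg: float = 26.0
    surge_amplitude_sd_mmHg: float = 4.3
    surge_amplitude_bounds_mmHg: Tuple[float, float] = (15.0, 60.0)
    upward_duration_range_s: Tuple[float, float] = (10.0, 40.0)
    downward_duration_range_s: Tuple[float, float] = (15.0, 60.0)
    confuser_rate_per_night: float = 30.0
    confuser_amplitude_range_mmHg: Tuple[float, float] = (5.0, 12.0)
    artifact_rate_per_night: float = 5.0
    artifact_magnitude_range_mmHg: Tuple[float, float] = (30.0, 80.0)
    sa_event_lead_s: float = 10.0             # PSG event ends this long before start
    psg_event_duration_range_s: Tuple[float, float] = (10.0, 60.0)
    negbin_dispersion: Optional[float] = None  # per-night count overdispersion
    seed: int = 0

    def validate(self) -> None:
        for name in ("sa_surge_rate_per_night", "nonsa_surge_rate_per_night",
                     "confuser_rate_per_night", "artifact_rate_per_night"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.surge_amplitude_bounds_mmHg
        if lo >= hi:
            raise ValueError("surge amplitude truncation bounds out of order")
        if lo < DetectorConfig().min_amplitude_mmHg:
            raise ValueError(
                "surge amplitude lower bound must be >= the default detector "
                "minimum amplitude so planted surges are detectable by "
                "construction"
            )
        for name in ("upward_duration_range_s", "downward_duration_range_s",
                     "confuser_amplitude_range_mmHg",
                     "artifact_magnitude_range_mmHg",
                     "psg_event_duration_range_s"):
            a, b = getattr(self, name)
            if a > b:
                raise ValueError(f"{name} out of order")
        if self.duration_s <= 0 or self.mean_beat_interval_s <= 0:
            raise ValueError("duration_s and mean_beat_interval_s must be > 0")


@dataclass
class PipelineConfig:
    """Top-level bundle of all stage configurations plus the global seed."""

    detector: DetectorConfig = field(default_factory=DetectorConfig)
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    matcher: MatchConfig = field(default_factory=MatchConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    def validate(self) -> None:
        self.detector.validate()
        self.learner.validate()
        self.matcher.validate()
        self.sim.validate()


_SECTIONS = {
    "detector": DetectorConfig,
    "learner": LearnerConfig,
    "matcher": MatchConfig,
    "sim": SimConfig,
}


def _from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in d:
            v = d[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


def config_to_dict(cfg: PipelineConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(d: dict) -> PipelineConfig:
    kwargs = {}
    for key, cls in _SECTIONS.items():
        if key in d:
            kwargs[key] = _from_dict(cls, d[key] or {})
    if "seed" in d:
        kwargs["seed"] = int(d["seed"])
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from YAML (or JSON) file."""
    import yaml

    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(data)


def save_config(cfg: PipelineConfig, path) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
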