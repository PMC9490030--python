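"""Run configuration: every tunable parameter with its standard default,
loadable from a YAML file with overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """All pipeline parameters (defaults are the standard values).

    Online and offline inference use different window widths, jitter factors
    and candidate thresholds; the offline center-spike search leaves
    candidates unrestricted (``theta_aggr_offline`` unset) to gather control
    samples for the batch AUC distribution.
    """

    # session / controller
    theta_trig: float = 0.99
    n_test: int = 200
    i_same: float = 1.0  # s
    i_diff: float = 0.5  # s
    latency_ms: float = 3.2
    t_range_ms: float = 30.0
    n_anti: int = 100
    duration_ms: float = 1.0  # D_i
    online_protocol: str = "I"
    # inference
    width_ms_online: float = 2.0
    width_ms_offline: float = 1.0
    w_jitter_online: float = 5.0
    w_jitter_offline: float = 4.0
    alpha_ms: float = 1.0
    theta_aggr_online: float = 0.98
    theta_aggr_offline: float | None = None
    theta_win: float = 5.0
    detect_sd: float = 5.0
    # judgment
    r_max_ms: float = 4.0
    min_triggers: int = 15
    jitter_criterion_ms: float = 0.25
    sigma_multiplier: float = 5.0
    no_trigger_cap: int = 10
    # simulator
    noise_sd: float = 1.0
    session_length: float = 850.0  # s
    fs: float = 20000.0
    n_tetrodes: int = 2
    n_sites: int = 3
    # default composition: 20 true projection pairs, ~20 synaptic-responder
    # pairs (6 responders x ~10/3 same-site targets) and 60 unrelated pairs
    # (6 unrelated units x 10 same-tetrode targets)
    n_projection: int = 20
    n_synaptic: int = 6
    n_unrelated: int = 6
    pattern_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.theta_trig < 1.0:
            raise ConfigError("theta_trig must lie in (0, 1)")
        if self.online_protocol not in ("I", "II"):
            raise ConfigError("online_protocol must be 'I' or 'II'")
        positive = (
            "n_test i_same i_diff t_range_ms n_anti duration_ms width_ms_online "
            "width_ms_offline w_jitter_online w_jitter_offline alpha_ms theta_win "
            "detect_sd r_max_ms min_triggers jitter_criterion_ms sigma_multiplier "
            "no_trigger_cap session_length fs n_tetrodes n_sites"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("latency_ms", "noise_sd", "pattern_noise_sd", "n_projection", "n_synaptic", "n_unrelated"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.theta_aggr_offline is not None and not 0.0 < self.theta_aggr_offline <= 1.0:
            raise ConfigError("theta_aggr_offline must lie in (0, 1]")
        if not 0.0 < self.theta_aggr_online <= 1.0:
            raise ConfigError("theta_aggr_online must lie in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a run configuration from a YAML file plus overrides.

    Absent keys take their defaults; override values win over the file; an
    unknown or out-of-range key raises :class:`ConfigError` naming it.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("configuration file must contain a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown configuration key {key!r}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def save_config(path, cfg: RunConfig) -> None:
    """Write the effective configuration beside outputs for provenance."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
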