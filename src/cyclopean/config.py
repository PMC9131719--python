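"""Run configuration: defaults, YAML loading, validation, round-tripping.

Every random operation in a run traces back to the single master ``seed``
via named substreams (subject x session x measure).  Units are degrees for
angles, cycles/degree for spatial frequencies, and minutes for times.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "CohortConfig", "ProtocolConfig", "StimulusConfig",
           "GridConfig", "StatsConfig", "ConfigError", "load_config",
           "save_config"]


class ConfigError(ValueError):
    """Itemized configuration schema violations."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))


@dataclass
class CohortConfig:
    model: str = "null"            # "null" or "deprivation"
    n: int = 10
    effect_mean: float = 19.2      # deg
    effect_sd: float = 7.0         # deg
    effect_tau: float = 15.0       # min
    iocsf_effect: float = 1.0
    baseline_phase_sd: float = 3.0  # deg
    phase_noise_sd: float = 4.0    # deg
    lapse: float = 0.04
    psychometric_slope: float = 3.5


@dataclass
class ProtocolConfig:
    session_times_min: dict = field(
        default_factory=lambda: {"pre": None, "post0": 0, "post10": 10,
                                 "post20": 20, "post30": 30, "post40": 40})
    phase_repetitions: int = 8
    qiocsf_trials: int = 100
    measures: list = field(default_factory=lambda: ["phase", "qiocsf"])
    theta0: float = 22.5           # deg
    contrast_ratio: float = 1.0


@dataclass
class StimulusConfig:
    extent_deg: float = 12.8
    pixels_per_degree: float = 40.0
    octave_bandwidth: float = 1.0
    grating_sf: float = 0.46       # c/d, phase-combination grating


@dataclass
class GridConfig:
    gamma_max_bounds: list = field(default_factory=lambda: [2.0, 200.0])
    gamma_max_n: int = 12
    f_max_bounds: list = field(default_factory=lambda: [0.5, 5.0])
    f_max_n: int = 12
    beta_bounds: list = field(default_factory=lambda: [1.0, 6.0])
    beta_n: int = 8
    delta_bounds: list = field(default_factory=lambda: [0.0, 1.5])
    delta_n: int = 8
    f_stim_bounds: list = field(default_factory=lambda: [0.94, 2.54])
    f_stim_n: int = 12
    m_stim_bounds: list = field(default_factory=lambda: [0.02, 1.0])
    m_stim_n: int = 25


@dataclass
class StatsConfig:
    tail: str = "one"              # power-analysis tail
    sphericity: str = "auto"       # "auto" | "always" | "never"
    alpha: float = 0.05


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return asdict(self)


def _apply(obj, data: dict, path: str, problems: list[str]):
    known = {f.name: f for f in fields(obj)}
    for key, value in data.items():
        if key not in known:
            problems.append(f"unknown key {path}{key}")
            continue
        current = getattr(obj, key)
        if is_dataclass(current):
            if not isinstance(value, dict):
                problems.append(f"{path}{key} must be a mapping")
            else:
                _apply(current, value, f"{path}{key}.", problems)
        else:
            setattr(obj, key, value)


def _validate(cfg: RunConfig, problems: list[str]) -> None:
    if cfg.cohort.model not in ("null", "deprivation"):
        problems.append("cohort.model must be 'null' or 'deprivation'")
    if cfg.cohort.n < 2:
        problems.append("cohort.n must be at least 2")
    if not 0.0 <= cfg.cohort.lapse < 0.1:
        problems.append("cohort.lapse must lie in [0, 0.1)")
    if cfg.cohort.effect_tau <= 0:
        problems.append("cohort.effect_tau must be positive")
    if not 0.0 < cfg.protocol.contrast_ratio <= 1.0:
        problems.append("protocol.contrast_ratio must lie in (0, 1]")
    if cfg.stats.tail not in ("one", "two"):
        problems.append("stats.tail must be 'one' or 'two'")
    if cfg.stats.sphericity not in ("auto", "always", "never"):
        problems.append("stats.sphericity must be 'auto', 'always' or 'never'")
    if not 0 < cfg.stats.alpha < 1:
        problems.append("stats.alpha must lie in (0, 1)")
    unknown = set(cfg.protocol.measures) - {"phase", "qiocsf"}
    if unknown:
        problems.append(f"protocol.measures has unknown entries {sorted(unknown)}")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config, filling defaults; unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(["top level of the config file must be a mapping"])
        data = loaded
    cfg = RunConfig()
    problems: list[str] = []
    _apply(cfg, data, "", problems)
    _validate(cfg, problems)
    if problems:
        raise ConfigError(problems)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return path
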