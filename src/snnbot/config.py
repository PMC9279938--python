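"""Run configuration: one structured document holding every tunable constant.

The defaults encode the reference parameter tables verbatim (neuron and
synapse constants, STDP amplitudes and time constants, the reward constants,
the distance-encoding constants) together with this package's documented
design constants (calibration setpoints, motion parameters, timings).  A
config file supplies partial overrides; unknown keys and out-of-range values
are rejected with their full key paths, all violations reported at once.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
import yaml

from .env_sim import MotionParams
from .network import CalibrationTargets, DecisionBands, EncoderParams, NetworkSpec
from .plasticity import PlasticityParams

__all__ = ["RunConfig", "ExperimentConfig", "load_config", "save_config", "default_config"]


@dataclass(frozen=True)
class ExperimentConfig:
    scenario: str = "single_left"
    trials: int = 3
    max_duration_s: float = 60.0
    course_max_duration_s: float = 180.0
    intertrial_s: float = 6.0       # idle time at clear range between trials
    pretrain_trials: int = 4        # per side, before a course run
    seed: int = 0
    sensor_noise_cm: float = 0.0    # uniform jitter half-width; 0 disables
    out_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.max_duration_s <= 0 or self.intertrial_s < 0:
            raise ValueError("durations must be positive")
        if self.sensor_noise_cm < 0:
            raise ValueError("sensor_noise_cm must be >= 0")


@dataclass(frozen=True)
class TimingConfig:
    dt: float = 0.1                # ms
    control_period: float = 100.0  # ms
    rate_window: float = 1000.0    # ms

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.control_period < self.dt or self.rate_window <= 0:
            raise ValueError("invalid timing configuration")


@dataclass(frozen=True)
class RunConfig:
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    encoder: EncoderParams = field(default_factory=EncoderParams)
    bands: DecisionBands = field(default_factory=DecisionBands)
    targets: CalibrationTargets = field(default_factory=CalibrationTargets)
    motion: MotionParams = field(default_factory=MotionParams)
    timing: TimingConfig = field(default_factory=TimingConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)

    def network_spec(self) -> NetworkSpec:
        return NetworkSpec(
            encoder=self.encoder,
            plasticity=self.plasticity,
            bands=self.bands,
            targets=self.targets,
            dt=self.timing.dt,
            control_period=self.timing.control_period,
            rate_window=self.timing.rate_window,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        # enums and other scalars are already plain in these frozen dataclasses
        return d


_SECTION_TYPES = {
    "plasticity": PlasticityParams,
    "encoder": EncoderParams,
    "bands": DecisionBands,
    "targets": CalibrationTargets,
    "motion": MotionParams,
    "timing": TimingConfig,
    "experiment": ExperimentConfig,
}


def default_config() -> RunConfig:
    return RunConfig()


def _build_section(name: str, cls, overrides: dict, errors: list[str]):
    known = {f.name for f in fields(cls)}
    clean = {}
    for key, value in overrides.items():
        if key not in known:
            errors.append(f"{name}.{key}: unknown key")
        else:
            clean[key] = value
    try:
        return cls(**clean)
    except (ValueError, TypeError) as exc:
        errors.append(f"{name}: {exc}")
        return cls()


def config_from_dict(data: dict) -> RunConfig:
    """Merge a (possibly partial) override mapping onto the defaults."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("configuration document must be a mapping")
    errors: list[str] = []
    sections = {}
    for key in data:
        if key not in _SECTION_TYPES:
            errors.append(f"{key}: unknown section (valid: {', '.join(_SECTION_TYPES)})")
    for name, cls in _SECTION_TYPES.items():
        overrides = data.get(name, {}) or {}
        if not isinstance(overrides, dict):
            errors.append(f"{name}: must be a mapping")
            overrides = {}
        sections[name] = _build_section(name, cls, overrides, errors)
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(**sections)


def load_config(path: str | Path | None) -> RunConfig:
    """Load defaults merged with the YAML override file at `path` (None or a
    missing 'overrides' document yields the pure defaults)."""
    if path is None:
        return default_config()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return config_from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
    return path
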