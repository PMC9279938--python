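"""Experiment orchestration: multi-trial learning runs, the multi-obstacle
course, trained-state snapshots, and log export.

The learning experiment repeats single-obstacle trials with the robot
repositioned at the start pose between trials while the network state
persists: weights relax back to baseline on their own (the forgetting term),
but the learning rates keep whatever they gained — which is exactly the
memory that makes later trials commit to avoidance earlier.  The course
experiment drives a pre-trained network through the five-obstacle slalom,
which must end with the brake, not a collision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import RunConfig, default_config
from .env_sim import TrialLog, make_scenario, run_closed_loop
from .network import NetworkRuntime, NetworkSpec, calibrate

__all__ = [
    "ExperimentSummary",
    "get_calibrated_spec",
    "run_learning_experiment",
    "run_course_experiment",
    "pretrain",
    "export_log",
    "save_trained_state",
    "load_trained_state",
]

_CAL_CACHE: dict[str, NetworkSpec] = {}


def get_calibrated_spec(cfg: RunConfig | None = None) -> NetworkSpec:
    """Calibrated network for this configuration (memoized per process)."""
    cfg = cfg or default_config()
    key = json.dumps(
        {k: v for k, v in cfg.to_dict().items() if k != "experiment"}, sort_keys=True
    )
    if key not in _CAL_CACHE:
        _CAL_CACHE[key] = calibrate(cfg.network_spec())
    return _CAL_CACHE[key]


@dataclass
class ExperimentSummary:
    """Digest of one experiment — a pure function of its trial logs."""

    scenario: str
    decision_times: list[float | None]
    terminal_causes: list[str]
    collision_count: int
    final_gamma12: float
    final_gamma34: float
    peak_w12: float
    peak_w34: float
    log_paths: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "decision_times_s": self.decision_times,
            "terminal_causes": self.terminal_causes,
            "collision_count": self.collision_count,
            "final_gamma12": self.final_gamma12,
            "final_gamma34": self.final_gamma34,
            "peak_w12": self.peak_w12,
            "peak_w34": self.peak_w34,
            "log_paths": self.log_paths,
        }


def _summarize(scenario: str, logs: list[TrialLog], runtime: NetworkRuntime) -> ExperimentSummary:
    return ExperimentSummary(
        scenario=scenario,
        decision_times=[log.decision_time() for log in logs],
        terminal_causes=[log.terminal_cause for log in logs],
        collision_count=sum(log.collision_time is not None for log in logs),
        final_gamma12=runtime.syn12.gamma,
        final_gamma34=runtime.syn34.gamma,
        peak_w12=max(max(log.w12, default=1.0) for log in logs),
        peak_w34=max(max(log.w34, default=1.0) for log in logs),
    )


def _idle(runtime: NetworkRuntime, spec: NetworkSpec, seconds: float) -> None:
    """Let the network run at clear range (repositioning interval)."""
    if seconds > 0:
        runtime.run(int(round(seconds * 1000.0 / spec.dt)),
                    spec.encoder.d_max, spec.encoder.d_max)


def run_learning_experiment(
    cfg: RunConfig,
    *,
    spec: NetworkSpec | None = None,
    runtime: NetworkRuntime | None = None,
    out_dir: str | Path | None = None,
) -> tuple[ExperimentSummary, list[TrialLog], NetworkRuntime]:
    """Consecutive single-obstacle trials with persistent network state."""
    exp = cfg.experiment
    if exp.scenario not in ("single_left", "single_right"):
        raise ValueError("learning experiment requires single_left or single_right")
    spec = spec or get_calibrated_spec(cfg)
    world, start = make_scenario(exp.scenario)
    runtime = runtime or NetworkRuntime(spec)
    logs = []
    for _ in range(exp.trials):
        log = run_closed_loop(
            spec, world, start, cfg.motion,
            max_duration=exp.max_duration_s, seed=exp.seed,
            runtime=runtime, sensor_noise_cm=exp.sensor_noise_cm,
        )
        logs.append(log)
        _idle(runtime, spec, exp.intertrial_s)
    summary = _summarize(exp.scenario, logs, runtime)
    if out_dir is not None:
        summary.log_paths = [
            str(p) for i, log in enumerate(logs)
            for p in export_log(log, Path(out_dir), stem=f"{exp.scenario}_trial{i + 1}")
        ]
    return summary, logs, runtime


def pretrain(
    cfg: RunConfig,
    *,
    spec: NetworkSpec | None = None,
    trials_per_side: int | None = None,
) -> NetworkRuntime:
    """Train both channels with alternating single-obstacle experiments."""
    spec = spec or get_calibrated_spec(cfg)
    runtime = NetworkRuntime(spec)
    n = trials_per_side if trials_per_side is not None else cfg.experiment.pretrain_trials
    for scenario in ("single_left", "single_right"):
        world, start = make_scenario(scenario)
        for _ in range(n):
            run_closed_loop(
                spec, world, start, cfg.motion,
                max_duration=cfg.experiment.max_duration_s,
                seed=cfg.experiment.seed, runtime=runtime,
            )
            _idle(runtime, spec, cfg.experiment.intertrial_s)
    # let the weights settle back to baseline before the next task
    _idle(runtime, spec, 8.0)
    return runtime


def run_course_experiment(
    cfg: RunConfig,
    *,
    spec: NetworkSpec | None = None,
    runtime: NetworkRuntime | None = None,
    out_dir: str | Path | None = None,
) -> tuple[ExperimentSummary, TrialLog, NetworkRuntime]:
    """Multi-obstacle slalom with a pre-trained network (trained in place if
    no runtime is supplied)."""
    spec = spec or get_calibrated_spec(cfg)
    if runtime is None:
        runtime = pretrain(cfg, spec=spec)
    world, start = make_scenario("slalom5")
    log = run_closed_loop(
        spec, world, start, cfg.motion,
        max_duration=cfg.experiment.course_max_duration_s, seed=cfg.experiment.seed,
        runtime=runtime, sensor_noise_cm=cfg.experiment.sensor_noise_cm,
    )
    summary = _summarize("slalom5", [log], runtime)
    if out_dir is not None:
        summary.log_paths = [str(p) for p in export_log(log, Path(out_dir), stem="slalom5")]
    return summary, log, runtime


def export_log(log: TrialLog, directory: str | Path, stem: str = "trial") -> list[Path]:
    """Write the time series (CSV, one row per control period) and a JSON
    summary; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frame = log_frame(log)
    csv_path = directory / f"{stem}.csv"
    frame.to_csv(csv_path, index=False)
    summary_path = directory / f"{stem}_summary.json"
    summary_path.write_text(json.dumps({
        "terminal_cause": log.terminal_cause,
        "collision_time_ms": log.collision_time,
        "stop_time_ms": log.stop_time,
        "decision_time_s": log.decision_time(),
        "n_periods": log.n_periods,
    }, indent=2))
    return [csv_path, summary_path]


def log_frame(log: TrialLog) -> pd.DataFrame:
    """The TrialLog as a DataFrame with the documented column order."""
    return pd.DataFrame({col: getattr(log, col) for col in TrialLog.COLUMNS})


def plot_log(log: TrialLog, directory: str | Path, stem: str = "trial") -> list[Path]:
    """Optional figure export (distance, weights, reward, Out rate).

    Imports matplotlib lazily so the core stays free of a plotting
    dependency.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = [x / 1000.0 for x in log.t]
    fig, axes = plt.subplots(4, 1, sharex=True, figsize=(8, 9))
    axes[0].plot(t, log.d_left, label="d_left")
    axes[0].plot(t, log.d_right, label="d_right")
    axes[0].set_ylabel("distance (cm)")
    axes[0].legend()
    axes[1].plot(t, log.w12, label="w12")
    axes[1].plot(t, log.w34, label="w34")
    axes[1].set_ylabel("weight")
    axes[1].legend()
    axes[2].plot(t, log.r1, label="r1")
    axes[2].plot(t, log.r2, label="r2")
    axes[2].set_ylabel("reward")
    axes[2].legend()
    axes[3].plot(t, log.out_rate)
    axes[3].set_ylabel("Out rate (Hz)")
    axes[3].set_xlabel("time (s)")
    path = Path(directory) / f"{stem}.png"
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return [path]


def save_trained_state(runtime: NetworkRuntime, path: str | Path) -> Path:
    """Snapshot of the long-term memory (learning rates) plus the calibration
    constants, as a structured text document."""
    path = Path(path)
    cal = runtime.spec.cal
    payload = {
        "gamma12": runtime.syn12.gamma,
        "gamma34": runtime.syn34.gamma,
        "calibration": {k: v for k, v in vars(cal).items()},
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_trained_state(spec: NetworkSpec, path: str | Path) -> NetworkRuntime:
    payload = json.loads(Path(path).read_text())
    runtime = NetworkRuntime(spec)
    runtime.syn12.gamma = float(payload["gamma12"])
    runtime.syn34.gamma = float(payload["gamma34"])
    return runtime
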