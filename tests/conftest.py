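"""Shared fixtures.

The calibrated network and the closed-loop experiment results are expensive
(seconds each), so they are built once per session and shared between the
module tests and the acceptance tests.
"""

from __future__ import annotations

import pytest

from snnbot.config import default_config
from snnbot.env_sim import make_scenario, run_closed_loop
from snnbot.experiments import (
    get_calibrated_spec,
    pretrain,
    run_course_experiment,
    run_learning_experiment,
)
from snnbot.network import NetworkRuntime


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def calibrated_spec(cfg):
    return get_calibrated_spec(cfg)


@pytest.fixture(scope="session")
def learning_results(cfg, calibrated_spec):
    """Three consecutive single_left trials from an untrained network."""
    summary, logs, runtime = run_learning_experiment(cfg, spec=calibrated_spec)
    return summary, logs, runtime


@pytest.fixture(scope="session")
def mirror_trials(cfg, calibrated_spec):
    """One untrained trial on each of the mirrored single-obstacle scenarios."""
    out = {}
    for scenario in ("single_left", "single_right"):
        world, start = make_scenario(scenario)
        runtime = NetworkRuntime(calibrated_spec)
        out[scenario] = run_closed_loop(
            calibrated_spec, world, start, cfg.motion,
            max_duration=cfg.experiment.max_duration_s, runtime=runtime,
        )
    return out


@pytest.fixture(scope="session")
def trained_runtime(cfg, calibrated_spec):
    return pretrain(cfg, spec=calibrated_spec)


@pytest.fixture(scope="session")
def course_results(cfg, calibrated_spec, trained_runtime):
    summary, log, runtime = run_course_experiment(
        cfg, spec=calibrated_spec, runtime=trained_runtime
    )
    return summary, log, runtime
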