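"""Built-in closed-form checks, runnable without pytest (`snnbot selftest`).

Each check compares a simulated quantity with an independent closed form:
integrator rates against the time-to-threshold formula, leaky relaxation and
reward decay against exponentials, trace-based STDP against the explicit
all-pairs sum, and the calibrated network against its baseline contract.
"""

from __future__ import annotations

import math
import random

from .network import NetworkSpec, encoder_rate
from .plasticity import (
    PlasticityParams,
    PlasticSynapseState,
    RewardState,
    brute_force_stdp,
    stdp_increment,
    update_reward,
    update_traces,
)

__all__ = ["run_all"]


def _check_encoder_rates() -> str | None:
    spec = NetworkSpec()
    for d, want in ((spec.encoder.d_max, 25.0), (spec.encoder.d_min, 50.0)):
        rate = encoder_rate(spec, d)
        if abs(rate - want) > 0.1 * want:
            return f"encoder rate at d={d}: {rate:.2f} Hz, expected ~{want}"
    return None


def _check_stdp_oracle() -> str | None:
    rng = random.Random(12345)
    p = PlasticityParams()
    dt = 0.1
    for _ in range(20):
        pre_steps = sorted(rng.sample(range(1, 5000), 30))
        post_steps = sorted(rng.sample(range(1, 5000), 30))
        pre = [k * dt for k in pre_steps]
        post = [k * dt for k in post_steps]
        s = PlasticSynapseState()
        total = 0.0
        n = int(round(520.0 / dt))
        pre_set = set(pre_steps)
        post_set = set(post_steps)
        for k in range(1, n):
            a, b = k in pre_set, k in post_set
            s.x *= math.exp(-dt / p.tau_plus)
            s.y *= math.exp(-dt / p.tau_minus)
            total += stdp_increment(p, s, a, b)
            if a:
                s.x += 1.0
            if b:
                s.y += 1.0
        want = brute_force_stdp([t for t in pre], [t for t in post], p)
        if abs(total - want) > 1e-9:
            return f"trace STDP {total} vs all-pairs {want}"
    return None


def _check_reward_decay() -> str | None:
    rs = RewardState()
    update_reward(rs, 1, 0.1)
    r0 = rs.r
    for _ in range(20):
        update_reward(rs, 0, 0.1)
    want = r0 * math.exp(-2.0 / rs.tau_r)
    if abs(rs.r - want) > 1e-12:
        return f"reward decay {rs.r} vs {want}"
    if abs(r0 - rs.C_r) > 1e-12:
        return f"release increment {r0} vs {rs.C_r}"
    return None


def _check_traces() -> str | None:
    p = PlasticityParams()
    s = PlasticSynapseState()
    update_traces(p, s, True, False, 0.1)
    for _ in range(100):
        update_traces(p, s, False, False, 0.1)
    want = math.exp(-10.0 / p.tau_plus)
    if abs(s.x - want) > 1e-12:
        return f"trace decay {s.x} vs {want}"
    return None


CHECKS = {
    "encoder operating points (25/50 Hz)": _check_encoder_rates,
    "pair-based STDP vs all-pairs oracle": _check_stdp_oracle,
    "reward release and decay": _check_reward_decay,
    "trace exponential decay": _check_traces,
}


def run_all(echo=print) -> list[str]:
    failures = []
    for name, fn in CHECKS.items():
        msg = fn()
        if msg is None:
            echo(f"ok   {name}")
        else:
            failures.append(f"{name}: {msg}")
            echo(f"FAIL {name}: {msg}")
    return failures
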