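"""Learning dynamics: pair-based STDP traces, eligibility, reward, and the
reward-modulated weight/learning-rate rule with a forgetting term.

Pair-based STDP keeps one exponentially decaying trace per side,

    dx/dt = −x/τ₊ + Σ δ(t − t_pre),      dy/dt = −y/τ₋ + Σ δ(t − t_post),

and converts coincidences into a weight-change term

    STDP(Δt) = A₋ · y(t) at each presynaptic spike
             + A₊ · x(t) at each postsynaptic spike,

which is the recursive form of the all-pairs sum Σ A₊ e^(−Δt/τ₊) (Δt > 0)
+ Σ A₋ e^(Δt/τ₋) (Δt < 0); `brute_force_stdp` implements that sum directly
as an independent oracle.  The STDP term does not act on the weight
immediately — it accumulates in an eligibility trace

    dc/dt = −c/τ_c + STDP(Δt) δ(t − t_spike),

which converts into weight change only in the presence of a reward signal

    dr/dt = −r/τ_r + C_r Σ δ(t − t_release).

The full rule adds a forgetting term pulling the weight back to its baseline
w0 and makes the learning rate itself plastic:

    dw/dt = γ(t) · r(t) · c(t) − (w − w0)/τ_w,
    dγ/dt = l · r(t) · c(t).

Because the weight always relaxes back to baseline once reward ceases, the
long-term memory of what was learned lives in γ, which only grows while
reward and eligibility coincide.  The classic reward-modulated rule
(dw/dt = γ·r·c with fixed γ) is kept as `classic_rstdp_step` for limit
checks: the full rule degenerates to it when 1/τ_w = 0 and l = 0.

Step-update order (one simulation step): spikes for this step are produced
first; traces then decay; the STDP term is evaluated with the decayed,
pre-jump traces (so a Δt = 0 pairing contributes nothing); traces jump;
eligibility and reward update; finally the weight/learning-rate rule runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "PlasticityParams",
    "PlasticSynapseState",
    "RewardState",
    "update_traces",
    "stdp_increment",
    "brute_force_stdp",
    "update_eligibility",
    "update_reward",
    "classic_rstdp_step",
    "improved_rule_step",
]


@dataclass
class PlasticityParams:
    """Constants of the learning rule.

    A_plus/A_minus, the trace constants and l carry the reference defaults
    (A₊ = 1, A₋ = −1, τ₊ = τ₋ = τ_c = 10 ms, l = 3e-5, w0 = 1).  τ_w and
    gamma0 have no published value; τ_w = 1000 ms reproduces the observed
    seconds-scale return of a learned weight to baseline after reward ends,
    and gamma0 ≈ √l balances within-trial weight growth against
    across-trial learning-rate growth (see docs/methods.md).
    """

    A_plus: float = 1.0
    A_minus: float = -1.0
    tau_plus: float = 10.0   # ms
    tau_minus: float = 10.0  # ms
    tau_c: float = 10.0      # ms
    tau_w: float = 2500.0    # ms; baseline-decay (forgetting) time constant
    w0: float = 1.0          # baseline weight
    l: float = 3e-5          # learning-rate gain constant
    gamma0: float = 0.005    # initial learning rate

    def __post_init__(self) -> None:
        for name in ("tau_plus", "tau_minus", "tau_c", "tau_w"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not (self.A_minus <= 0.0 <= self.A_plus):
            raise ValueError("require A_minus <= 0 <= A_plus")
        if self.gamma0 < 0:
            raise ValueError("gamma0 must be >= 0")


@dataclass
class PlasticSynapseState:
    """Dynamic variables of one modifiable synapse."""

    w: float = 1.0       # weight (clamped at >= 0)
    x: float = 0.0       # presynaptic trace
    y: float = 0.0       # postsynaptic trace
    c: float = 0.0       # eligibility trace
    gamma: float = 0.005  # learning rate

    @classmethod
    def from_params(cls, p: PlasticityParams) -> "PlasticSynapseState":
        return cls(w=p.w0, gamma=p.gamma0)


@dataclass
class RewardState:
    """A decaying reward variable fed by discrete release events."""

    r: float = 0.0
    tau_r: float = 2.0    # ms
    C_r: float = 0.07     # per-release increment
    release_times: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.tau_r) and self.tau_r > 0):
            raise ValueError("tau_r must be finite and > 0")


def update_traces(
    p: PlasticityParams,
    s: PlasticSynapseState,
    pre_spiked: bool,
    post_spiked: bool,
    dt: float,
) -> PlasticSynapseState:
    """Decay both traces, then apply the unit Dirac increments."""
    s.x *= math.exp(-dt / p.tau_plus)
    s.y *= math.exp(-dt / p.tau_minus)
    if pre_spiked:
        s.x += 1.0
    if post_spiked:
        s.y += 1.0
    return s


def stdp_increment(
    p: PlasticityParams,
    s: PlasticSynapseState,
    pre_spiked: bool,
    post_spiked: bool,
) -> float:
    """STDP(Δt) for the current step, evaluated on pre-jump traces.

    Callers must invoke this *after* decaying the traces but *before*
    applying this step's unit increments (see module docstring).
    """
    inc = 0.0
    if pre_spiked:
        inc += p.A_minus * s.y
    if post_spiked:
        inc += p.A_plus * s.x
    return inc


def brute_force_stdp(
    pre_times: list[float],
    post_times: list[float],
    p: PlasticityParams,
) -> float:
    """All-pairs STDP sum; quadratic-cost oracle used only in tests.

    Pairs with Δt = t_post − t_pre = 0 contribute nothing, matching the
    pre-jump trace convention of `stdp_increment`.
    """
    total = 0.0
    for tp in pre_times:
        for tq in post_times:
            delta = tq - tp
            if delta > 0:
                total += p.A_plus * math.exp(-delta / p.tau_plus)
            elif delta < 0:
                total += p.A_minus * math.exp(delta / p.tau_minus)
    return total


def update_eligibility(
    p: PlasticityParams,
    s: PlasticSynapseState,
    increment: float,
    dt: float,
) -> PlasticSynapseState:
    s.c *= math.exp(-dt / p.tau_c)
    s.c += increment
    return s


def update_reward(rs: RewardState, n_releases: int, dt: float, t: float | None = None) -> RewardState:
    """Decay r and add C_r per release event this step."""
    if n_releases < 0:
        raise ValueError("n_releases must be >= 0")
    rs.r *= math.exp(-dt / rs.tau_r)
    if n_releases:
        rs.r += rs.C_r * n_releases
        if t is not None:
            rs.release_times.extend([t] * n_releases)
    return rs


def classic_rstdp_step(
    s: PlasticSynapseState,
    r: float,
    dt: float,
) -> PlasticSynapseState:
    """Reference reward-modulated step with fixed learning rate: dw = γ·r·c·dt."""
    s.w += s.gamma * r * s.c * dt
    return s


def improved_rule_step(
    p: PlasticityParams,
    s: PlasticSynapseState,
    r: float,
    dt: float,
) -> PlasticSynapseState:
    """One step of the full rule: reward-gated growth, baseline decay, and
    learning-rate consolidation.  The weight is clamped at zero so a synapse
    can never silently flip polarity."""
    s.w += s.gamma * r * s.c * dt - (s.w - p.w0) / p.tau_w * dt
    if s.w < 0.0:
        s.w = 0.0
    s.gamma += p.l * r * s.c * dt
    return s
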