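"""The ten-neuron obstacle-avoidance network: architecture, simulation
engine, dopaminergic reward gating, rate decoding, and calibration.

Architecture (two mirror-symmetric halves plus a brake sub-network):

* ``Left`` / ``Right`` — integrator neurons encoding the two ultrasonic
  distance readings into regular spike trains via the affine current map
  I = gain · (I0 − C_i · d), 25 Hz at maximum range and 50 Hz at minimum.
* ``N1`` / ``N3`` — pacemaker relays: leaky neurons with a calibrated
  constant bias current firing at 25 Hz.
* ``N2`` / ``N4`` — relay neurons driven through the two *plastic* synapses
  w12 (N1→N2) and w34 (N3→N4).  At the baseline weight each pacemaker spike
  elicits exactly one relay spike; as the weight grows past a calibrated
  onset the relay answers with spike doublets/triplets, i.e. its rate jumps
  from 25 Hz toward 50–75 Hz.  The relay rate is the quantity the decision
  neuron reads.
* ``R1`` / ``R2`` — dopaminergic release units (leaky neurons whose
  threshold crossings emit reward releases instead of spikes).  R2 listens
  to the *left* sensor current and to N4 spikes; R1 to the *right* sensor
  and N2.  The gate is conjunctive by calibration: sensor drive near the
  50 Hz end of the range or relay spikes alone stay subthreshold — only
  their coincidence releases reward.
* ``Out`` — decision neuron with a calibrated bias.  N2→Out is excitatory
  and N4→Out inhibitory, so a left-side obstacle (which grows w34 and the
  N4 rate) pulls the Out rate *below* the straight band (turn right) and a
  right-side obstacle pushes it above (turn left).
* ``Stop`` — brake neuron excited by both encoders; calibrated so that one
  sensor at 50 Hz (with the other at 25 Hz) can never fire it, while both
  at 50 Hz fire it within half a second.

Commands are decoded from the Out rate over a sliding window: straight in
the closed band [8, 18] Hz, left above, right below, with an active Stop
overriding everything.

All constants that the reference tables do not publish (encoder gain,
pacemaker and Out bias, relay drive scale, gate and brake weights) are
produced by :func:`calibrate`, which is deterministic: closed forms where
available, bisection on simulated rates otherwise, followed by verification
of every contract.  The calibration setpoints themselves are documented in
``docs/methods.md``.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from enum import Enum

from .neuro_core import (
    NeuronParams,
    NeuronState,
    Polarity,
    SynapseParams,
    SynapseState,
    if_step,
    lif_step,
    synapse_step,
)
from .plasticity import (
    PlasticityParams,
    PlasticSynapseState,
    RewardState,
    update_reward,
)

__all__ = [
    "Command",
    "EncoderParams",
    "DecisionBands",
    "NetworkSpec",
    "NetworkRuntime",
    "TelemetrySample",
    "CalibrationError",
    "encode_distance",
    "build_network",
    "calibrate",
    "estimate_rate",
    "decode_action",
    "dopamine_gate_step",
    "network_step",
]

V_TH = 30.0
DT_DEFAULT = 0.1  # ms

NEURON_NAMES = ("Left", "Right", "N1", "N2", "N3", "N4", "R1", "R2", "Out", "Stop")


class Command(str, Enum):
    STRAIGHT = "straight"
    LEFT = "left"
    RIGHT = "right"
    STOP = "stop"


@dataclass(frozen=True)
class EncoderParams:
    """Distance-to-current map I = gain · (I0 − C_i·d), d clipped to range."""

    I0: float = 0.225    # nA
    C_i: float = 0.005   # nA/cm
    d_min: float = 15.0  # cm
    d_max: float = 30.0  # cm
    gain: float = 10.0   # reconciles table constants with the 25/50 Hz operating points

    def __post_init__(self) -> None:
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be < d_max")
        if self.I0 - self.C_i * self.d_max <= 0:
            raise ValueError("current at d_max must stay positive")


def encode_distance(ep: EncoderParams, d_left: float, d_right: float) -> tuple[float, float]:
    """Clip each reading to [d_min, d_max] and apply the affine current map."""
    out = []
    for d in (d_left, d_right):
        if not math.isfinite(d) or d < 0:
            raise ValueError(f"distance must be finite and non-negative, got {d!r}")
        d = min(max(d, ep.d_min), ep.d_max)
        out.append(ep.gain * (ep.I0 - ep.C_i * d))
    return out[0], out[1]


@dataclass(frozen=True)
class DecisionBands:
    low_hz: float = 8.0
    high_hz: float = 18.0


def decode_action(out_rate: float, stop_active: bool, bands: DecisionBands = DecisionBands()) -> Command:
    """Map the Out firing rate to a motion command (band-inclusive straight);
    an active brake dominates every rate."""
    if out_rate < 0:
        raise ValueError("out_rate must be >= 0")
    if stop_active:
        return Command.STOP
    if out_rate > bands.high_hz:
        return Command.LEFT
    if out_rate < bands.low_hz:
        return Command.RIGHT
    return Command.STRAIGHT


def estimate_rate(spike_times: list[float], t_now: float, window: float) -> float:
    """Spike count in (t_now − window, t_now], divided by the window, in Hz."""
    if window <= 0:
        raise ValueError("window must be > 0")
    lo = bisect_right(spike_times, t_now - window)
    hi = bisect_right(spike_times, t_now)
    return (hi - lo) / window * 1000.0


@dataclass
class CalibrationConstants:
    """Inferred operating-point constants filled in by :func:`calibrate`."""

    pacemaker_bias: float = 0.0   # nA, drives N1/N3 at 25 Hz
    relay_scale: float = 0.0      # multiplies w·A on the plastic synapses
    g_trigger: float = 0.0        # pacemaker→relay trigger synapse weight
    out_bias: float = 0.0         # nA, holds the baseline Out rate at ~12 Hz
    g_exc_out: float = 0.0        # N2→Out static weight
    g_inh_out: float = 0.0        # N4→Out static weight
    g_stop: float = 0.0           # encoder→Stop static weights
    g_sense: float = 0.0          # sensor-current share into R1/R2
    g_pulse: float = 0.0          # relay→R pulse synapse weight
    calibrated: bool = False


@dataclass(frozen=True)
class CalibrationTargets:
    """Setpoints the calibration drives toward (see docs/methods.md).

    The pacemaker→relay coupling is split into two components.  A strong,
    fast *trigger* synapse (sub-millisecond time constant, suprathreshold in
    a single step) makes the relay fire exactly one step after each
    pacemaker spike irrespective of the plastic weight, so in the
    one-spike-per-volley regime the two relay trains are step-aligned for
    any pair of weights near baseline.  The *plastic* synapse's residual
    current alone determines whether a second (burst) spike follows the
    refractory period; its drive scale is bisected so the burst onset sits
    at `relay_burst_onset_w`.

    The two Out synapses carry *equal* weights: at and near baseline the
    aligned relay volleys cancel exactly and Out free-runs on its bias
    (closed form for the 12 Hz midband rate).  Engagement breaks the
    cancellation with one-sided doublet spikes: on the inhibited side each
    doublet knocks the free-run back below threshold (Out silenced), on the
    excited side each doublet fires Out (≈25 Hz, volley-locked).
    """

    baseline_out_hz: float = 12.0
    relay_burst_onset_w: float = 1.020  # plastic weight at which the relay rate leaves 25 Hz
    engaged_w: float = 1.10           # reference engaged weight for verification
    trigger_step_v: float = 32.0      # mV: one-step depolarisation from the trigger synapse
    trigger_tau_s: float = 0.5        # ms: trigger current dies before the refractory ends
    out_kick_v: float = 16.0          # mV: peak Out deflection per one-sided relay spike
    out_tau_s: float = 1.0            # ms: fast Out kernel — a kick is over before the
                                      # refractory ends, so excitation volley-locks at 25 Hz
                                      # while any periodic knock still silences the free-run
    gate_sense_v: float = 12.0        # mV steady gate drive from a sensor at d_max
    gate_pulse_peak_v: float = 10.0   # mV peak gate drive from one relay spike
    gate_pulse_tau_s: float = 2.0     # ms, pulse synapse time constant (short enough
                                      # that the two pulses of a relay doublet do not
                                      # superpose — reward needs sensor proximity, not
                                      # merely an engaged relay)
    stop_tau_s: float = 40.0          # ms: the brake integrates mean encoder drive, so
                                      # its threshold does not depend on the relative
                                      # phase of the two spike trains
    stop_fire_within_ms: float = 500.0


@dataclass
class NetworkSpec:
    """Complete parameterisation of the ten-neuron controller."""

    encoder: EncoderParams = field(default_factory=EncoderParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    bands: DecisionBands = field(default_factory=DecisionBands)
    tau_s: float = 10.0           # ms, synaptic current constant for ordinary synapses
    gain_A: float = 0.5           # per-spike accumulation constant
    tau_r: float = 2.0            # ms, reward decay
    C_r: float = 0.07             # per-release reward increment
    dt: float = DT_DEFAULT        # ms
    rate_window: float = 1000.0   # ms, sliding window of the rate decoder
    control_period: float = 100.0  # ms
    neuron_leaky_tau: float = 5.0
    neuron_leaky_t_ref: float = 2.0
    neuron_if_tau: float = 1.0
    R_membrane: float = 1.0
    targets: CalibrationTargets = field(default_factory=CalibrationTargets)
    cal: CalibrationConstants = field(default_factory=CalibrationConstants)

    # -- structural description (fixed architecture) --------------------
    @property
    def neuron_names(self) -> tuple[str, ...]:
        return NEURON_NAMES

    @property
    def plastic_synapses(self) -> dict[str, tuple[str, str]]:
        return {"w12": ("N1", "N2"), "w34": ("N3", "N4")}

    @property
    def reward_channels(self) -> dict[str, dict[str, str]]:
        """Channel → its sensor source, paired relay, and target synapse."""
        return {
            "R1": {"sensor": "Right", "relay": "N2", "synapse": "w12"},
            "R2": {"sensor": "Left", "relay": "N4", "synapse": "w34"},
        }

    @property
    def static_synapses(self) -> dict[tuple[str, str], tuple[str, Polarity]]:
        """(pre, post) → (weight constant name, polarity)."""
        return {
            ("N2", "Out"): ("g_exc_out", Polarity.EXCITATORY),
            ("N4", "Out"): ("g_inh_out", Polarity.INHIBITORY),
            ("Left", "Stop"): ("g_stop", Polarity.EXCITATORY),
            ("Right", "Stop"): ("g_stop", Polarity.EXCITATORY),
            ("N2", "R1"): ("g_pulse", Polarity.EXCITATORY),
            ("N4", "R2"): ("g_pulse", Polarity.EXCITATORY),
        }

    @property
    def trigger_synapses(self) -> dict[tuple[str, str], str]:
        """Fast static transmission component parallel to each plastic synapse."""
        return {("N1", "N2"): "g_trigger", ("N3", "N4"): "g_trigger"}

    def neuron_params(self, name: str) -> NeuronParams:
        if name in ("Left", "Right"):
            return NeuronParams.integrator(tau=self.neuron_if_tau, R=self.R_membrane)
        bias = 0.0
        if name in ("N1", "N3"):
            bias = self.cal.pacemaker_bias
        elif name == "Out":
            bias = self.cal.out_bias
        return NeuronParams.leaky(
            tau=self.neuron_leaky_tau,
            R=self.R_membrane,
            t_ref=self.neuron_leaky_t_ref,
            bias_current=bias,
        )

    def mirrored(self) -> "NetworkSpec":
        """The reflection of the architecture: swapping (Left, N1, N2, R1)
        with (Right, N3, N4, R2) maps the spec onto itself, exchanging the
        two plastic synapses and reward channels (the Out polarities swap
        with the halves, which is what turns a left avoidance into a right
        one)."""
        return replace(self)

    def validate(self) -> None:
        errors = []
        if len(self.neuron_names) != 10:
            errors.append("architecture must have exactly 10 neuron units")
        if len(self.plastic_synapses) != 2:
            errors.append("exactly 2 plastic synapses required")
        if len(self.reward_channels) != 2:
            errors.append("exactly 2 reward channels required")
        if self.tau_s <= 0:
            errors.append("tau_s must be > 0")
        if self.dt <= 0:
            errors.append("dt must be > 0")
        if not self.bands.low_hz < self.bands.high_hz:
            errors.append("decision bands must satisfy low < high")
        if self.control_period < self.dt:
            errors.append("control_period must be >= dt")
        if errors:
            raise ValueError("invalid network spec: " + "; ".join(errors))


def build_network(config=None) -> NetworkSpec:
    """Construct the (uncalibrated) reference architecture.

    `config` may be a RunConfig-like object carrying encoder/plasticity/
    band/timing fields; omitted fields fall back to the reference defaults.
    """
    if config is None:
        spec = NetworkSpec()
    else:
        spec = NetworkSpec(
            encoder=getattr(config, "encoder", EncoderParams()),
            plasticity=getattr(config, "plasticity", PlasticityParams()),
            bands=getattr(config, "bands", DecisionBands()),
            dt=getattr(config, "dt", DT_DEFAULT),
            rate_window=getattr(config, "rate_window", 1000.0),
            control_period=getattr(config, "control_period", 100.0),
        )
    spec.validate()
    return spec


@dataclass
class TelemetrySample:
    """Instantaneous network telemetry, emitted once per control period."""

    t: float
    w12: float
    w34: float
    gamma12: float
    gamma34: float
    r1: float
    r2: float
    out_rate: float
    stop_active: bool
    releases_r1: int
    releases_r2: int
    out_spikes: int


def dopamine_gate_step(
    neuron_params: NeuronParams,
    neuron_state: NeuronState,
    pulse_params: SynapseParams,
    pulse_state: SynapseState,
    reward: RewardState,
    sensor_drive: float,
    paired_relay_spiked: bool,
    g_pulse: float,
    t: float,
    dt: float,
) -> bool:
    """Single-step reference update of one dopaminergic channel.

    The release unit integrates the sensor current plus a pulse synapse fed
    by its paired relay; a threshold crossing emits one release into the
    channel's reward variable (and resets the unit).  The engine performs
    identical arithmetic inline; this op exists for unit-level contracts.
    The relay spike flag carries the usual one-step propagation delay
    (caller passes the previous step's spike).
    """
    synapse_step(pulse_params, pulse_state, paired_relay_spiked, g_pulse, dt)
    _, released = lif_step(
        neuron_params, neuron_state, sensor_drive + pulse_state.I_syn, t, dt
    )
    update_reward(reward, 1 if released else 0, dt, t=t + dt)
    return released


class NetworkRuntime:
    """Mutable simulation state plus the (hand-specialised) stepping engine.

    The engine advances every unit with the exact update rules of
    ``neuro_core``/``plasticity``; tests verify its equivalence to composing
    those scalar ops.  Spike propagation carries a one-step delay, so the
    update order within a step is deterministic: synaptic currents ingest
    the previous step's spikes, neurons fire, then traces, eligibility,
    reward, and the plasticity rule run.
    """

    def __init__(self, spec: NetworkSpec):
        if not spec.cal.calibrated:
            raise ValueError("runtime requires a calibrated spec (run calibrate() first)")
        spec.validate()
        self.spec = spec
        self.t = 0.0
        self.plastic_enabled = True
        p = spec.plasticity
        # neuron state: v, refractory, prev_spiked
        self.v = {n: 0.0 for n in NEURON_NAMES}
        self.refrac = {n: 0.0 for n in NEURON_NAMES}
        self.prev_spiked = {n: False for n in NEURON_NAMES}
        # synaptic currents
        self.I_12 = 0.0
        self.I_34 = 0.0
        self.I_t12 = 0.0
        self.I_t34 = 0.0
        self.I_2out = 0.0
        self.I_4out = 0.0
        self.I_lstop = 0.0
        self.I_rstop = 0.0
        self.I_2r1 = 0.0
        self.I_4r2 = 0.0
        # plastic synapse states and reward channels
        self.syn12 = PlasticSynapseState.from_params(p)
        self.syn34 = PlasticSynapseState.from_params(p)
        self.rw1 = RewardState(tau_r=spec.tau_r, C_r=spec.C_r)
        self.rw2 = RewardState(tau_r=spec.tau_r, C_r=spec.C_r)
        # spike books
        self.out_spikes: list[float] = []
        self.stop_spikes: list[float] = []
        self.spike_counts = {n: 0 for n in NEURON_NAMES}

    # -- helpers -------------------------------------------------------
    def set_weights(self, w12: float | None = None, w34: float | None = None) -> None:
        if w12 is not None:
            self.syn12.w = w12
        if w34 is not None:
            self.syn34.w = w34

    def out_rate(self, window: float | None = None) -> float:
        return estimate_rate(self.out_spikes, self.t, window or self.spec.rate_window)

    def stop_active(self, lookback: float | None = None) -> bool:
        lb = lookback if lookback is not None else self.spec.control_period
        return bool(self.stop_spikes) and self.stop_spikes[-1] > self.t - lb

    def run(self, n_steps: int, d_left: float, d_right: float) -> tuple[int, int, int]:
        """Advance the whole network `n_steps` at fixed sensor readings.

        Returns (reward releases on R1, on R2, Out spikes) over the run.
        Hot loop: locals are hoisted and decay factors precomputed.
        """
        spec = self.spec
        dt = spec.dt
        cal = spec.cal
        p = spec.plasticity
        I_left, I_right = encode_distance(spec.encoder, d_left, d_right)

        # decay factors
        k_syn = math.exp(-dt / spec.tau_s)
        k_trig = math.exp(-dt / spec.targets.trigger_tau_s)
        k_out = math.exp(-dt / spec.targets.out_tau_s)
        k_stop = math.exp(-dt / spec.targets.stop_tau_s)
        k_pulse = math.exp(-dt / spec.targets.gate_pulse_tau_s)
        k_lif = math.exp(-dt / spec.neuron_leaky_tau)
        k_x = math.exp(-dt / p.tau_plus)
        k_y = math.exp(-dt / p.tau_minus)
        k_c = math.exp(-dt / p.tau_c)
        k_r = math.exp(-dt / spec.tau_r)
        k_w = dt / p.tau_w

        A = spec.gain_A
        relay_scale = cal.relay_scale
        j_trig = cal.g_trigger * A
        j_exc = cal.g_exc_out * A
        j_inh = cal.g_inh_out * A
        j_stop = cal.g_stop * A
        j_pulse = cal.g_pulse * A
        g_sense = cal.g_sense
        drive_if = dt / spec.neuron_if_tau * spec.R_membrane
        drive_lif = dt * spec.R_membrane / spec.neuron_leaky_tau
        t_ref = spec.neuron_leaky_t_ref
        pm_bias = cal.pacemaker_bias
        out_bias = cal.out_bias
        C_r = spec.C_r
        l_rate = p.l
        A_plus, A_minus, w0 = p.A_plus, p.A_minus, p.w0
        plastic_on = self.plastic_enabled

        v = self.v
        refrac = self.refrac
        vL, vR = v["Left"], v["Right"]
        vN1, vN2, vN3, vN4 = v["N1"], v["N2"], v["N3"], v["N4"]
        vR1, vR2, vOut, vStop = v["R1"], v["R2"], v["Out"], v["Stop"]
        rfN1, rfN2, rfN3, rfN4 = refrac["N1"], refrac["N2"], refrac["N3"], refrac["N4"]
        rfR1, rfR2, rfOut, rfStop = refrac["R1"], refrac["R2"], refrac["Out"], refrac["Stop"]
        ps = self.prev_spiked
        sL, sR = ps["Left"], ps["Right"]
        sN1, sN2, sN3, sN4 = ps["N1"], ps["N2"], ps["N3"], ps["N4"]
        sR1, sR2, sOut, sStop = ps["R1"], ps["R2"], ps["Out"], ps["Stop"]

        I_12, I_34 = self.I_12, self.I_34
        I_t12, I_t34 = self.I_t12, self.I_t34
        I_2out, I_4out = self.I_2out, self.I_4out
        I_lstop, I_rstop = self.I_lstop, self.I_rstop
        I_2r1, I_4r2 = self.I_2r1, self.I_4r2

        s12, s34 = self.syn12, self.syn34
        w12, x12, y12, c12, g12 = s12.w, s12.x, s12.y, s12.c, s12.gamma
        w34, x34, y34, c34, g34 = s34.w, s34.x, s34.y, s34.c, s34.gamma
        r1, r2 = self.rw1.r, self.rw2.r

        out_spikes = self.out_spikes
        stop_spikes = self.stop_spikes
        t = self.t
        n_rel1 = n_rel2 = n_out = 0
        counts = self.spike_counts
        cL = cR = cN1 = cN2 = cN3 = cN4 = cStop = 0

        sense_r1 = g_sense * I_right
        sense_r2 = g_sense * I_left

        for _ in range(n_steps):
            # 1. synaptic currents ingest last step's spikes
            I_12 = I_12 * k_syn + (w12 * A * relay_scale if sN1 else 0.0)
            I_34 = I_34 * k_syn + (w34 * A * relay_scale if sN3 else 0.0)
            I_t12 = I_t12 * k_trig + (j_trig if sN1 else 0.0)
            I_t34 = I_t34 * k_trig + (j_trig if sN3 else 0.0)
            I_2out = I_2out * k_out + (j_exc if sN2 else 0.0)
            I_4out = I_4out * k_out + (j_inh if sN4 else 0.0)
            I_lstop = I_lstop * k_stop + (j_stop if sL else 0.0)
            I_rstop = I_rstop * k_stop + (j_stop if sR else 0.0)
            I_2r1 = I_2r1 * k_pulse + (j_pulse if sN2 else 0.0)
            I_4r2 = I_4r2 * k_pulse + (j_pulse if sN4 else 0.0)

            t += dt

            # 2. encoders (pure integrators, no refractory period)
            vL += drive_if * I_left
            sL = vL >= V_TH
            if sL:
                vL = 0.0
                cL += 1
            vR += drive_if * I_right
            sR = vR >= V_TH
            if sR:
                vR = 0.0
                cR += 1

            # 3. leaky units (refractory: hold at rest, ignore input)
            if rfN1 > 0.0:
                rfN1 -= dt
                vN1 = 0.0
                sN1 = False
            else:
                vN1 = vN1 * k_lif + drive_lif * pm_bias
                sN1 = vN1 >= V_TH
                if sN1:
                    vN1 = 0.0
                    rfN1 = t_ref
                    cN1 += 1
            if rfN2 > 0.0:
                rfN2 -= dt
                vN2 = 0.0
                sN2 = False
            else:
                vN2 = vN2 * k_lif + drive_lif * (I_12 + I_t12)
                sN2 = vN2 >= V_TH
                if sN2:
                    vN2 = 0.0
                    rfN2 = t_ref
                    cN2 += 1
            if rfN3 > 0.0:
                rfN3 -= dt
                vN3 = 0.0
                sN3 = False
            else:
                vN3 = vN3 * k_lif + drive_lif * pm_bias
                sN3 = vN3 >= V_TH
                if sN3:
                    vN3 = 0.0
                    rfN3 = t_ref
                    cN3 += 1
            if rfN4 > 0.0:
                rfN4 -= dt
                vN4 = 0.0
                sN4 = False
            else:
                vN4 = vN4 * k_lif + drive_lif * (I_34 + I_t34)
                sN4 = vN4 >= V_TH
                if sN4:
                    vN4 = 0.0
                    rfN4 = t_ref
                    cN4 += 1
            # dopaminergic units: threshold crossings are reward releases
            if rfR1 > 0.0:
                rfR1 -= dt
                vR1 = 0.0
                sR1 = False
            else:
                vR1 = vR1 * k_lif + drive_lif * (sense_r1 + I_2r1)
                sR1 = vR1 >= V_TH
                if sR1:
                    vR1 = 0.0
                    rfR1 = t_ref
                    n_rel1 += 1
            if rfR2 > 0.0:
                rfR2 -= dt
                vR2 = 0.0
                sR2 = False
            else:
                vR2 = vR2 * k_lif + drive_lif * (sense_r2 + I_4r2)
                sR2 = vR2 >= V_TH
                if sR2:
                    vR2 = 0.0
                    rfR2 = t_ref
                    n_rel2 += 1
            if rfOut > 0.0:
                rfOut -= dt
                vOut = 0.0
                sOut = False
            else:
                vOut = vOut * k_lif + drive_lif * (out_bias + I_2out - I_4out)
                sOut = vOut >= V_TH
                if sOut:
                    vOut = 0.0
                    rfOut = t_ref
                    out_spikes.append(t)
                    n_out += 1
            if rfStop > 0.0:
                rfStop -= dt
                vStop = 0.0
                sStop = False
            else:
                vStop = vStop * k_lif + drive_lif * (I_lstop + I_rstop)
                sStop = vStop >= V_TH
                if sStop:
                    vStop = 0.0
                    rfStop = t_ref
                    stop_spikes.append(t)
                    cStop += 1

            # 4. plasticity: traces decay, STDP on pre-jump traces, jumps,
            #    eligibility, reward, then the weight/learning-rate rule.
            x12 *= k_x
            y12 *= k_y
            inc12 = 0.0
            if sN1:
                inc12 += A_minus * y12
            if sN2:
                inc12 += A_plus * x12
            if sN1:
                x12 += 1.0
            if sN2:
                y12 += 1.0
            c12 = c12 * k_c + inc12

            x34 *= k_x
            y34 *= k_y
            inc34 = 0.0
            if sN3:
                inc34 += A_minus * y34
            if sN4:
                inc34 += A_plus * x34
            if sN3:
                x34 += 1.0
            if sN4:
                y34 += 1.0
            c34 = c34 * k_c + inc34

            r1 *= k_r
            if sR1:
                r1 += C_r
            r2 *= k_r
            if sR2:
                r2 += C_r

            if plastic_on:
                w12 += g12 * r1 * c12 * dt - (w12 - w0) * k_w
                if w12 < 0.0:
                    w12 = 0.0
                g12 += l_rate * r1 * c12 * dt
                w34 += g34 * r2 * c34 * dt - (w34 - w0) * k_w
                if w34 < 0.0:
                    w34 = 0.0
                g34 += l_rate * r2 * c34 * dt

        # write back
        v["Left"], v["Right"] = vL, vR
        v["N1"], v["N2"], v["N3"], v["N4"] = vN1, vN2, vN3, vN4
        v["R1"], v["R2"], v["Out"], v["Stop"] = vR1, vR2, vOut, vStop
        refrac["N1"], refrac["N2"], refrac["N3"], refrac["N4"] = rfN1, rfN2, rfN3, rfN4
        refrac["R1"], refrac["R2"], refrac["Out"], refrac["Stop"] = rfR1, rfR2, rfOut, rfStop
        ps["Left"], ps["Right"] = sL, sR
        ps["N1"], ps["N2"], ps["N3"], ps["N4"] = sN1, sN2, sN3, sN4
        ps["R1"], ps["R2"], ps["Out"], ps["Stop"] = sR1, sR2, sOut, sStop
        self.I_12, self.I_34 = I_12, I_34
        self.I_t12, self.I_t34 = I_t12, I_t34
        self.I_2out, self.I_4out = I_2out, I_4out
        self.I_lstop, self.I_rstop = I_lstop, I_rstop
        self.I_2r1, self.I_4r2 = I_2r1, I_4r2
        s12.w, s12.x, s12.y, s12.c, s12.gamma = w12, x12, y12, c12, g12
        s34.w, s34.x, s34.y, s34.c, s34.gamma = w34, x34, y34, c34, g34
        self.rw1.r, self.rw2.r = r1, r2
        self.t = t
        counts["Left"] += cL
        counts["Right"] += cR
        counts["N1"] += cN1
        counts["N2"] += cN2
        counts["N3"] += cN3
        counts["N4"] += cN4
        counts["Out"] += n_out
        counts["Stop"] += cStop
        counts["R1"] += n_rel1
        counts["R2"] += n_rel2
        return n_rel1, n_rel2, n_out

    def run_control_period(self, d_left: float, d_right: float) -> TelemetrySample:
        """Advance one control period and emit telemetry."""
        spec = self.spec
        n_steps = int(round(spec.control_period / spec.dt))
        rel1, rel2, n_out = self.run(n_steps, d_left, d_right)
        return TelemetrySample(
            t=self.t,
            w12=self.syn12.w,
            w34=self.syn34.w,
            gamma12=self.syn12.gamma,
            gamma34=self.syn34.gamma,
            r1=self.rw1.r,
            r2=self.rw2.r,
            out_rate=self.out_rate(),
            stop_active=self.stop_active(),
            releases_r1=rel1,
            releases_r2=rel2,
            out_spikes=n_out,
        )


def network_step(
    spec: NetworkSpec,
    runtime: NetworkRuntime,
    d_left: float,
    d_right: float,
    dt: float | None = None,
) -> tuple[NetworkRuntime, TelemetrySample]:
    """Advance the full network by a single dt (contract-level op)."""
    if dt is not None and not math.isclose(dt, spec.dt):
        raise ValueError("dt must match the spec's simulation step")
    rel1, rel2, n_out = runtime.run(1, d_left, d_right)
    sample = TelemetrySample(
        t=runtime.t,
        w12=runtime.syn12.w,
        w34=runtime.syn34.w,
        gamma12=runtime.syn12.gamma,
        gamma34=runtime.syn34.gamma,
        r1=runtime.rw1.r,
        r2=runtime.rw2.r,
        out_rate=runtime.out_rate(),
        stop_active=runtime.stop_active(),
        releases_r1=rel1,
        releases_r2=rel2,
        out_spikes=n_out,
    )
    return runtime, sample


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


class CalibrationError(RuntimeError):
    """A calibration setpoint could not be met; the message names it."""


def _pacemaker_bias_closed_form(spec: NetworkSpec, rate_hz: float = 25.0) -> float:
    """Bias current giving a leaky unit the exact discrete period 1/rate.

    The discrete subthreshold map is v' = v·α + b with α = exp(−dt/τ) and
    b = dt·R·I/τ; starting from reset, v_m = b(1−α^m)/(1−α).  The period is
    t_ref plus m steps, so pick I such that the threshold is crossed exactly
    at the required m (using m − 1/2 centres the crossing inside the step).
    """
    dt, tau, R = spec.dt, spec.neuron_leaky_tau, spec.R_membrane
    alpha = math.exp(-dt / tau)
    period_steps = int(round(1000.0 / rate_hz / dt))
    ref_steps = int(round(spec.neuron_leaky_t_ref / dt))
    m = period_steps - ref_steps
    b = V_TH * (1.0 - alpha) / (1.0 - alpha ** (m - 0.5))
    return b * tau / (dt * R)


def _spike_rate_lif_chain(
    spec: NetworkSpec,
    cal: CalibrationConstants,
    *,
    w12: float,
    w34: float,
    duration_ms: float,
    d_left: float | None = None,
    d_right: float | None = None,
) -> dict[str, float]:
    """Simulate the full network with plasticity frozen and given weights;
    return spike counts per neuron (used by the calibration bisections)."""
    trial = replace(spec, cal=replace(cal, calibrated=True))
    rt = NetworkRuntime(trial)
    rt.plastic_enabled = False
    rt.set_weights(w12=w12, w34=w34)
    dl = d_left if d_left is not None else spec.encoder.d_max
    dr = d_right if d_right is not None else spec.encoder.d_max
    n = int(round(duration_ms / spec.dt))
    rt.run(n, dl, dr)
    return dict(rt.spike_counts)


def _bisect(f, lo: float, hi: float, n_iter: int = 40, rising: bool = True) -> float:
    """Boundary of a monotone boolean predicate on [lo, hi]."""
    flo, fhi = f(lo), f(hi)
    if flo == fhi:
        raise CalibrationError(f"bisection bracket [{lo}, {hi}] does not straddle the setpoint")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if f(mid) == flo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate(spec: NetworkSpec, *, full_check: bool = True) -> NetworkSpec:
    """Fix every inferred operating-point constant and verify the contracts.

    Deterministic: closed forms for the encoder gain and pacemaker bias,
    bisection on simulated rates for the relay scale, the Out pathway, and
    the brake, and direct construction plus verification for the
    dopaminergic gates.  Raises :class:`CalibrationError` naming the first
    setpoint that cannot be met.
    """
    spec.validate()
    tg = spec.targets
    enc = spec.encoder
    dt = spec.dt
    cal = CalibrationConstants()

    # (a) pacemaker bias — closed form, verified by simulation
    cal.pacemaker_bias = _pacemaker_bias_closed_form(spec)

    # (b) relay coupling.  The trigger weight is fixed by its one-step
    # depolarisation setpoint; the plastic drive scale is the smallest value
    # at which the relay leaves the one-spike-per-volley regime at the burst
    # onset weight.  Verify strict 1:1 following across the whole baseline
    # neighbourhood (relay spike on the step after each pacemaker spike).
    kappa = dt / (spec.neuron_leaky_tau * (1.0 - math.exp(-dt / spec.neuron_leaky_tau)))
    cal.g_trigger = tg.trigger_step_v * spec.neuron_leaky_tau / (
        dt * spec.R_membrane * spec.gain_A
    )

    def relay_rate(scale: float, w: float, dur: float = 2000.0) -> float:
        c = replace(cal, relay_scale=scale, calibrated=True)
        counts = _relay_subcircuit_counts(spec, c, w, dur)
        return counts / dur * 1000.0

    def bursts_at_onset(scale: float) -> bool:
        return relay_rate(scale, tg.relay_burst_onset_w) > 27.0

    scale_on = _bisect(bursts_at_onset, 10.0, 400.0)
    cal.relay_scale = scale_on * 1.001
    for w_chk in (1.0, 0.5 + 0.5 * tg.relay_burst_onset_w):
        if abs(relay_rate(cal.relay_scale, w_chk, 4000.0) - 25.0) > 0.3:
            raise CalibrationError(
                f"relay does not follow the pacemaker 1:1 at w={w_chk:.3f}"
            )
    if relay_rate(cal.relay_scale, tg.engaged_w, 4000.0) < 40.0:
        raise CalibrationError("relay rate does not rise into the engaged regime at the reference weight")

    # (c) dopaminergic gate: sensor share and relay pulse from the voltage
    # setpoints (quasi-steady sensor contribution; single-pulse peak).
    I_dmax = enc.gain * (enc.I0 - enc.C_i * enc.d_max)
    cal.g_sense = tg.gate_sense_v / (I_dmax * kappa)
    # peak of the pulse response for tau_s == tau_m is J/e; general two-
    # exponential peak otherwise
    tau_m, tau_p = spec.neuron_leaky_tau, tg.gate_pulse_tau_s
    if math.isclose(tau_p, tau_m):
        peak_factor = math.exp(-1.0)
    else:
        tpk = math.log(tau_m / tau_p) / (1.0 / tau_p - 1.0 / tau_m)
        peak_factor = (tau_p / (tau_m - tau_p)) * (
            math.exp(-tpk / tau_m) - math.exp(-tpk / tau_p)
        )
    cal.g_pulse = tg.gate_pulse_peak_v / peak_factor / spec.gain_A

    # (d) Out pathway.  Baseline: the aligned relay volleys cancel exactly,
    # so the bias has the same closed form as the pacemaker, at the midband
    # rate.  The shared synaptic gain follows from the per-spike kick
    # setpoint (the kick must robustly silence the free-run on the
    # inhibitory side and fire it on the excitatory side); the engaged rates
    # are then verified rather than searched.
    cal.out_bias = _pacemaker_bias_closed_form(spec, rate_hz=tg.baseline_out_hz)
    # peak of the exponential-synapse voltage response per unit jump
    tau_m = spec.neuron_leaky_tau
    tau_o = tg.out_tau_s
    t_peak = math.log(tau_o / tau_m) / (1.0 / tau_m - 1.0 / tau_o)
    peak_out = (tau_o / (tau_m - tau_o)) * (
        math.exp(-t_peak / tau_m) - math.exp(-t_peak / tau_o)
    )
    cal.g_exc_out = cal.g_inh_out = tg.out_kick_v / (peak_out * spec.gain_A)

    def out_rate(w12: float, w34: float, dur: float = 4000.0) -> float:
        c = replace(cal, calibrated=True)
        counts = _spike_rate_lif_chain(spec, c, w12=w12, w34=w34, duration_ms=dur)
        return counts["Out"] / dur * 1000.0

    w_eng = tg.engaged_w
    r_exc = out_rate(w_eng, 1.0)
    r_inh = out_rate(1.0, w_eng)
    r_base = out_rate(1.0, 1.0, dur=10000.0)
    if not (23.0 <= r_exc <= 27.0):
        raise CalibrationError(f"excited Out rate {r_exc:.2f} Hz is not volley-locked")
    if r_inh > 4.0:
        raise CalibrationError(f"inhibited Out rate {r_inh:.2f} Hz is not silenced")
    if abs(r_base - tg.baseline_out_hz) > 0.15:
        raise CalibrationError(f"baseline Out rate {r_base:.2f} Hz off the straight-band midpoint")

    # (e) brake.  The encoder spike trains reaching Stop carry an arbitrary
    # relative phase, so the firing threshold is set against the *worst*
    # case (anti-phase trains, lowest drive peaks) at a bilateral reading
    # just above d_min, and silence under unilateral / oblique readings is
    # verified against the *best* case (synchronized trains, highest peaks).
    def stop_count(g, d_left, d_right, dur, antiphase):
        return _stop_subcircuit_counts(spec, g, d_left, d_right, dur, antiphase)

    d_both = enc.d_min + (1.0 / 15.0) * (enc.d_max - enc.d_min)
    cal.g_stop = _bisect(
        lambda g: stop_count(g, d_both, d_both, 1000.0, True) > 0, 1.0, 100.0
    )
    d_mixed = enc.d_min + 0.6 * (enc.d_max - enc.d_min)
    for d_l, d_r in ((enc.d_min, d_mixed), (enc.d_min, enc.d_max), (21.0, 21.0)):
        if stop_count(cal.g_stop, d_l, d_r, 5000.0, False) > 0:
            raise CalibrationError(
                f"brake fires under non-bilateral proximity ({d_l:g}, {d_r:g}) cm"
            )
    if stop_count(cal.g_stop, enc.d_min, enc.d_min, tg.stop_fire_within_ms, True) == 0:
        raise CalibrationError("brake does not fire fast enough under bilateral proximity")

    # (f) full-network baseline check: with plasticity active and both
    # sensors at maximum range the Out count over 10 s must sit on the
    # straight-band midpoint.
    cal.calibrated = True
    rt = NetworkRuntime(replace(spec, cal=cal))
    rt.run(int(round(10000.0 / dt)), enc.d_max, enc.d_max)
    target_count = int(round(tg.baseline_out_hz * 10.0))
    if abs(len(rt.out_spikes) - target_count) > 1:
        raise CalibrationError(
            f"full-network baseline Out count {len(rt.out_spikes)} over 10 s, expected ~{target_count}"
        )

    out = replace(spec, cal=cal)
    if full_check:
        _verify_contracts(out)
    return out


def _relay_subcircuit_counts(
    spec: NetworkSpec, cal: CalibrationConstants, w: float, duration_ms: float
) -> int:
    """Pacemaker→relay pair in isolation; returns relay spike count."""
    dt = spec.dt
    k_syn = math.exp(-dt / spec.tau_s)
    k_trig = math.exp(-dt / spec.targets.trigger_tau_s)
    k_lif = math.exp(-dt / spec.neuron_leaky_tau)
    drive = dt * spec.R_membrane / spec.neuron_leaky_tau
    bias = cal.pacemaker_bias
    jump = w * spec.gain_A * cal.relay_scale
    jump_t = cal.g_trigger * spec.gain_A
    t_ref = spec.neuron_leaky_t_ref
    v1 = v2 = 0.0
    rf1 = rf2 = 0.0
    s1 = False
    I = 0.0
    It = 0.0
    n2 = 0
    for _ in range(int(round(duration_ms / dt))):
        I = I * k_syn + (jump if s1 else 0.0)
        It = It * k_trig + (jump_t if s1 else 0.0)
        if rf1 > 0.0:
            rf1 -= dt
            v1 = 0.0
            s1 = False
        else:
            v1 = v1 * k_lif + drive * bias
            s1 = v1 >= V_TH
            if s1:
                v1 = 0.0
                rf1 = t_ref
        if rf2 > 0.0:
            rf2 -= dt
            v2 = 0.0
        else:
            v2 = v2 * k_lif + drive * (I + It)
            if v2 >= V_TH:
                v2 = 0.0
                rf2 = t_ref
                n2 += 1
    return n2


def _stop_subcircuit_counts(
    spec: NetworkSpec,
    g_stop: float,
    d_left: float,
    d_right: float,
    duration_ms: float,
    antiphase: bool,
) -> int:
    """Two encoders plus the brake neuron; returns Stop spike count.

    With `antiphase` the right encoder starts half-way to threshold, which
    at equal readings yields maximally interleaved spike trains.
    """
    dt = spec.dt
    I_l, I_r = encode_distance(spec.encoder, d_left, d_right)
    k_stop = math.exp(-dt / spec.targets.stop_tau_s)
    k_lif = math.exp(-dt / spec.neuron_leaky_tau)
    drive_if = dt * spec.R_membrane / spec.neuron_if_tau
    drive_lif = dt * spec.R_membrane / spec.neuron_leaky_tau
    jump = g_stop * spec.gain_A
    t_ref = spec.neuron_leaky_t_ref
    vl, vr, vs = 0.0, (0.5 * V_TH if antiphase else 0.0), 0.0
    rf = 0.0
    sl = sr = False
    Il = Ir = 0.0
    n = 0
    for _ in range(int(round(duration_ms / dt))):
        Il = Il * k_stop + (jump if sl else 0.0)
        Ir = Ir * k_stop + (jump if sr else 0.0)
        vl += drive_if * I_l
        sl = vl >= V_TH
        if sl:
            vl = 0.0
        vr += drive_if * I_r
        sr = vr >= V_TH
        if sr:
            vr = 0.0
        if rf > 0.0:
            rf -= dt
            vs = 0.0
        else:
            vs = vs * k_lif + drive_lif * (Il + Ir)
            if vs >= V_TH:
                vs = 0.0
                rf = t_ref
                n += 1
    return n


def _verify_contracts(spec: NetworkSpec) -> None:
    """Post-calibration verification of the operating contracts."""
    enc = spec.encoder
    failures = []

    # encoder operating points (closed-loop of the integrator alone)
    for d, want in ((enc.d_max, 25.0), (enc.d_min, 50.0)):
        rate = encoder_rate(spec, d, duration_ms=4000.0)
        if abs(rate - want) > 0.1 * want:
            failures.append(f"encoder at d={d} cm fires {rate:.2f} Hz, expected ~{want} Hz")

    # baseline: no releases, weights pinned at w0
    rt = NetworkRuntime(spec)
    n = int(round(5000.0 / spec.dt))
    rel1, rel2, _ = rt.run(n, enc.d_max, enc.d_max)
    if rel1 or rel2:
        failures.append("reward released at baseline (both sensors at d_max)")
    if abs(rt.syn12.w - spec.plasticity.w0) > 1e-9 or abs(rt.syn34.w - spec.plasticity.w0) > 1e-9:
        failures.append("weights drifted at baseline")
    base_rate = len(rt.out_spikes) / 5.0
    if not (spec.bands.low_hz <= base_rate <= spec.bands.high_hz):
        failures.append(f"baseline Out rate {base_rate:.2f} Hz outside the straight band")
    if rt.stop_spikes:
        failures.append("brake fired at baseline")

    # gate activation: left proximity produces releases within 200 ms
    rt = NetworkRuntime(spec)
    rt.run(int(round(200.0 / spec.dt)), enc.d_min, enc.d_max)
    if rt.spike_counts["R2"] < 1:
        failures.append("left-proximity gate failed to release within 200 ms")
    if rt.spike_counts["R1"] > 0:
        failures.append("wrong-side channel released under left proximity")

    # brake contracts
    rt = NetworkRuntime(spec)
    rt.plastic_enabled = False
    rt.run(int(round(5000.0 / spec.dt)), enc.d_min, enc.d_max)
    if rt.stop_spikes:
        failures.append("brake fired under unilateral proximity")
    rt = NetworkRuntime(spec)
    rt.plastic_enabled = False
    rt.run(int(round(spec.targets.stop_fire_within_ms / spec.dt)), enc.d_min, enc.d_min)
    if not rt.stop_spikes:
        failures.append("brake failed to fire under bilateral proximity")

    if failures:
        raise CalibrationError("; ".join(failures))


def encoder_rate(spec: NetworkSpec, d: float, duration_ms: float = 4000.0) -> float:
    """Firing rate of one encoding integrator at a fixed distance."""
    I, _ = encode_distance(spec.encoder, d, d)
    p = NeuronParams.integrator(tau=spec.neuron_if_tau, R=spec.R_membrane)
    st = NeuronState()
    n = int(round(duration_ms / spec.dt))
    t = 0.0
    for _ in range(n):
        if_step(p, st, I, t, spec.dt)
        t += spec.dt
    return len(st.spike_times) / duration_ms * 1000.0
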