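# snnbot

A clock-driven spiking-neural-network simulator for a small autonomous
robot controller that *learns* obstacle avoidance, built around
reward-modulated spike-timing-dependent plasticity (R-STDP) with two
biologically motivated extensions: a forgetting term that relaxes each
synaptic weight back to its baseline, and an adaptive learning rate that
accumulates the reward history and serves as the network's long-term
memory. Reward is not injected by the experimenter — it is released by
dopaminergic neurons inside the network whenever sensory proximity and
relay activity coincide.

The package is aimed at computational-neuroscience and neurorobotics work:
it provides the neuron/synapse/plasticity primitives, the complete
ten-neuron obstacle-avoidance architecture, a deterministic 2D closed-loop
robot environment, and the two standard experiments (multi-trial learning
on a single obstacle; a five-obstacle course ending in a braking stop).

## The model

Neurons are integrate-and-fire units (threshold 30 mV, reset to rest):
pure integrators encode the two sonar distances as spike trains via
I = gain·(I0 − C_i·d) (25 Hz at 30 cm, 50 Hz at 15 cm), and leaky units
(τ_m = 5 ms, 2 ms refractory) do everything else. Synapses are
exponential-current synapses, τ_s dI/dt = −I + Σ w·A·δ(t − t_pre).

Learning is pair-based STDP read through an eligibility trace and gated by
reward:

    dx/dt = −x/τ₊ + Σδ(t−t_pre)          (pre trace; y analogous)
    dc/dt = −c/τ_c + STDP(Δt)·δ          (eligibility)
    dr/dt = −r/τ_r + C_r·Σδ(t−t_rel)     (reward, released by R1/R2)

    dw/dt = γ(t)·r(t)·c(t) − (w − w0)/τ_w
    dγ/dt = l·r(t)·c(t)

Weights always return to baseline after reward ceases (so a turn ends and
the robot can go straight again), while γ only grows — each successful
avoidance makes the next decision faster. The network maps the decision
neuron's firing rate to commands: 8–18 Hz straight, above 18 Hz turn left,
below 8 Hz turn right, and a brake neuron that fires only when *both*
sensors read near minimum range stops the robot.

## Worked example

```python
from snnbot.config import default_config
from snnbot.experiments import get_calibrated_spec, run_learning_experiment

cfg = default_config()                 # reference constants + documented defaults
spec = get_calibrated_spec(cfg)        # deterministic calibration (~seconds)
summary, logs, runtime = run_learning_experiment(cfg, spec=spec)
print(summary.decision_times)          # [2.4, 2.2, 2.0]  (seconds, strictly decreasing)
print(summary.terminal_causes)         # ['collision', 'completed', 'completed']
print(round(summary.final_gamma34, 6)) # 0.006172  (grew from gamma0 = 0.005)
```

Three consecutive trials against the same left-side obstacle: the naive
controller only commits to a right turn 2.4 s after the first reward
release — after it has already hit the carton — while the second and third
trials turn early enough to clear it, with strictly shorter decision times
and a strictly larger learning rate after every trial. The same thing from
the shell:

```
snnbot run-trial --scenario single_left --trials 3 --seed 1 --out runs/
snnbot run-course --seed 1 --out runs/      # five-obstacle course, ends in "stop"
snnbot calibrate                            # print the inferred constants
snnbot export-defaults                      # write the full default config as YAML
snnbot selftest                             # closed-form and oracle checks
```

`run-course` pre-trains both channels (four trials per side by default),
then drives the slalom: the summary reports zero collisions and a terminal
cause of `stop`, triggered when both sonars simultaneously read ≈15–17 cm
in front of the final double-width carton.

Logs are plain CSV (one row per 100 ms control period: distances, both
weights, both learning rates, reward variables, Out rate, command, pose)
plus a JSON summary, so every figure-style quantity can be re-plotted
directly; `snnbot.experiments.plot_log` renders the standard four-panel
view if matplotlib is installed.

## Layout

- `snnbot.neuro_core` — IF/LIF neurons and the exponential synapse.
- `snnbot.plasticity` — traces, eligibility, reward, the classic R-STDP
  rule and the full rule with forgetting + adaptive learning rate.
- `snnbot.network` — the ten-neuron architecture, the simulation engine,
  dopaminergic gating, rate decoding, and deterministic calibration.
- `snnbot.env_sim` — 2D world, raycast sonars, unicycle robot, closed loop.
- `snnbot.config` / `snnbot.experiments` / `snnbot.cli` — configuration,
  the two experiments, log export, command-line entry points.

`docs/methods.md` documents the model equations, every inferred constant
and its rationale, the calibration procedure, and known limitations.
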