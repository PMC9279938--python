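# Methods

This note documents the models implemented in `snnbot`, the constants they
use, the calibration that fixes the constants no reference table publishes,
and what the synthetic 2D environment does and does not capture.

## Unit system and integration scheme

All quantities live in mV / ms / nA / MΩ, so a product R·I is directly a
voltage in mV. The simulation is clock-driven with a fixed step
dt = 0.1 ms. Every pure-decay term (membrane leak, synaptic current,
spike traces, eligibility, reward) uses the exact one-step factor
exp(−dt/τ); drive terms enter by forward Euler. The scheme is first order:
halving dt moves a leaky-membrane trajectory by well under 1 % of the 30 mV
threshold (asserted in the tests). One consequence worth knowing: the
discrete subthreshold fixed point is R·I·(dt/τ)/(1 − e^(−dt/τ)) ≈ 1.01·R·I
at dt = 0.1 ms, τ = 5 ms — about 1 % above the continuous value. The
calibration works directly on the discrete system, so this bias is absorbed
rather than corrected.

Spike propagation carries a one-step delay: synaptic currents at step n
ingest the spikes of step n−1. Within a step the order is fixed — synapses,
then neurons (a threshold crossing registers at the end of the step, the
potential resets to rest in the same step), then plasticity (traces decay,
the pair term is evaluated on the decayed pre-jump traces, traces jump,
eligibility and reward update, the weight/learning-rate rule runs last).
This order makes a Δt = 0 pre/post pairing contribute nothing.

## Neurons and synapses

Two models. The *integrator* (τ = 1 ms, R = 1 MΩ, no refractory period)
encodes each sonar reading as a regular spike train via the affine map
I = gain·(I0 − C_i·d), with I0 = 0.225 nA, C_i = 0.005 nA/cm and readings
clipped into [15, 30] cm. With the table constants alone the encoder would
fire at 2.5–5 Hz; a fixed gain of 10 reconciles the current map with the
stated 25 Hz (at 30 cm) and 50 Hz (at 15 cm) operating points. The *leaky*
model (τ = 5 ms, R = 1 MΩ, 2 ms refractory period, input ignored while
refractory) serves every other unit. Both share a 30 mV threshold and a
0 mV resting potential. The integrator's drift is implemented literally as
(v_rest + R·I)/τ; with v_rest = 0 this is the standard non-leaky
integrator, and the distinction would matter only for nonzero resting
potentials.

Synaptic current is a first-order exponential kernel (τ_s = 10 ms unless a
component documents otherwise): each presynaptic spike adds weight × A to
the current, with the accumulation constant A = 0.5; inhibitory synapses
deliver their current negated. The kernel is sometimes called an alpha
synapse in the field's older literature, but the equation integrated here
is the first-order exponential, not the second-order alpha function.

## Plasticity

Pair-based STDP with one trace per side (τ₊ = τ₋ = 10 ms, A₊ = 1,
A₋ = −1), accumulated into an eligibility trace (τ_c = 10 ms) rather than
applied to the weight. The eligibility converts into weight change only in
the presence of the reward variable r(t), which decays with τ_r = 2 ms and
jumps by C_r = 0.07 per release of a dopaminergic unit. The full rule is

    dw/dt = γ(t)·r(t)·c(t) − (w − w0)/τ_w,       dγ/dt = l·r(t)·c(t),

with w0 = 1 and l = 3·10⁻⁵. The forgetting term returns the weight to
baseline once reward ceases, so the durable memory of learning lives in the
learning rate γ, which can only grow (there is no punishment channel and
reward is non-negative). Weights are clamped at zero — a negative weight
would silently flip a synapse's polarity. γ is not capped; the experiment
durations keep it small.

Two constants of the rule have no published value and are design choices:

* **τ_w = 2500 ms.** The avoidance turn lasts roughly as long as the weight
  stays above the relay burst onset after reward ceases, i.e. a few times
  shorter than τ_w; 2.5 s gives 30–60° avoidance turns at the default turn
  rate and returns a weight to within 1 % of baseline in ~10 s, consistent
  with an avoidance episode that ends seconds after the obstacle clears.
* **γ0 = 0.005.** With l fixed, the weight change over an encounter scales
  as γ0·S and the learning-rate change as l·S, where S = ∫r·c dt. Both are
  of order unity in their own terms only when γ0 ≈ √l; 0.005 makes a naive
  controller's first encounter fail (decision after contact), while the
  ~10–15 % per-trial growth of γ turns later encounters into pre-contact
  avoidances. A γ0 of order 1 would make the relative learning-rate growth
  ~10⁻⁴ per trial — numerically invisible at the 100 ms control
  resolution.

## The ten-neuron controller

Left/Right encoders; two pacemaker relays N1/N3 (leaky units with a
calibrated constant bias holding them at exactly 25 Hz — a passive leaky
unit cannot fire without input); relay neurons N2/N4 behind the two plastic
synapses w12 (N1→N2) and w34 (N3→N4); dopaminergic units R1/R2; the
decision neuron Out; the brake neuron Stop.

**Relay coupling.** The pacemaker→relay coupling is split into a strong,
fast *trigger* synapse (one-step suprathreshold, τ_s = 0.5 ms — its current
is gone before the refractory period ends) and the plastic synapse, whose
residual current alone determines whether a *second* spike follows the
refractory period. Consequences: (a) the relay fires exactly one spike, one
step after each pacemaker spike, for any weight near baseline — the two
relay trains are perfectly step-aligned; (b) the plastic weight controls a
sharp burst onset (calibrated to w = 1.020) above which the relay answers
each volley with a doublet, i.e. its rate jumps 25 → 50 Hz. The trigger is
an inferred component of the same kind as the encoder gain and the Out
bias: the reference architecture states the operating points but not the
drive magnitudes that realize them.

**Decision pathway.** N2→Out is excitatory and N4→Out inhibitory, with
*equal* weights and a fast kernel (τ = 1 ms, per-spike peak 16 mV at Out).
A right-side obstacle therefore raises the Out rate (turn left) and a
left-side obstacle lowers it (turn right), matching the functional
narrative of the source system (its two descriptions of these polarities
contradict each other; the turn directions are the authoritative
constraint). At baseline the two aligned relay volleys cancel *exactly* and
Out free-runs on its closed-form bias at ~12 Hz, the midpoint of the
[8, 18] Hz straight band. This cancellation is the load-bearing design: a
leaky unit firing at 12 Hz sits microvolts from threshold between spikes,
so any residual input ripple would entrain it toward 25 Hz; step-aligned
volleys make the residual exactly zero. During engagement the one-sided
doublet spikes either fire Out on every volley (≈25 Hz, excited side) or
knock the free-run back each cycle (≈0 Hz, inhibited side — recovery to
threshold takes ~78 ms, longer than the 40 ms between knocks). The fast
kernel matters on the excited side: a slow tail would keep the
near-threshold unit firing in bursts.

Commands are decoded from a 1000 ms sliding window over Out spikes,
re-evaluated every 100 ms control period; 8 and 18 Hz map inclusively to
straight; an active brake (a Stop spike within the last control period)
dominates. Because the straight band is asymmetric around 12 Hz (4 Hz below,
6 Hz above) while the engaged rates are 0 and 25 Hz, the window-averaged
rate leaves the band ~130 ms earlier under inhibition than under
excitation: mirrored trials differ by about one control period in turn
onset. Everything upstream of the command is exactly mirror-symmetric (see
below).

**Dopaminergic gating.** Each release unit (a leaky neuron whose threshold
crossings emit reward releases instead of spikes) sums a share of its
sensor's encoder *current* (12 mV quasi-steady at 30 cm, hence 24 mV at
15 cm) and a pulse synapse from its paired relay (10 mV peak, τ = 2 ms —
short enough that the two pulses of a doublet do not stack). Neither input
alone reaches the 30 mV threshold; their conjunction does once the sensor
reads roughly 23 cm or less. Releases therefore require *simultaneous*
sensor proximity and relay activity, and reward stops soon after the
obstacle leaves the ray. Per the architecture, each channel's reward acts
only on its own plastic synapse.

**Brake.** Stop sums both encoders through slow synapses (τ = 40 ms), so
it thresholds on the *mean* drive and is insensitive to the relative phase
of the two spike trains. Its weight is calibrated at the firing boundary
for both sensors reading 16 cm with worst-case (anti-phase) trains, and
verified silent for unilateral and oblique mixed readings with best-case
(synchronized) trains. Face-on bilateral approach at 15 cm fires it within
~100 ms.

## Calibration

`calibrate()` is deterministic and ordered: (a) pacemaker and Out bias by
the closed form for an exact discrete firing period; (b) the plastic drive
scale by bisection on the burst-onset weight, with 1:1 following verified
at and between the baseline and the onset; (c) the gate constants from the
voltage setpoints above, with the release contracts verified by simulation;
(d) the Out synapse weight from the per-spike kick setpoint, with the
baseline/engaged rates verified; (e) the brake weight by bisection as
described. Any missed setpoint raises an error naming it. Calibration of
the default configuration takes a few seconds and is memoized per process.

## Environment and experiments

The world is a continuous cm-scale plane with axis-aligned rectangular
obstacles. The robot is a disc (radius 5 cm) with unicycle kinematics and
two single-ray sonars at ±30°; readings are ray-to-rectangle distances
clipped into [15, 30] cm. Defaults: 4 cm/s forward speed and 0.25 rad/s
turn rate — the platform's drivetrain is unpublished, and these values put
the first encounter of a naive controller just beyond its reaction time
(collision) while a trained one clears it, reproducing the qualitative
failure-then-success progression. The control loop exchanges sensor
readings and commands every 100 ms; on a collision the pose freezes while
the network keeps running until it commits to its first turn, because the
interesting quantity of a failed trial is precisely the decision that
arrives after contact. Every run is bit-reproducible; optional uniform
sensor jitter (off by default) is driven by the run's seed.

The learning experiment repeats single-obstacle trials with the robot
repositioned between trials and ~6 s of idle time; weights relax back on
their own, learning rates persist. The *decision time* reported per trial
is the interval from the first reward release to the first non-straight
command — the reaction-time analogue of the weight-rise time in the source
experiments, whose absolute values depend on the unpublished robot speed
and are not reproduced; only their strictly decreasing ordering is. The
five-obstacle course places four alternating single cartons along the
trained robot's weave and a double-width fifth carton across the path; a
pre-trained controller (default: four trials per side) completes it with
no collision and ends with a brake, with both readings near the minimum
range.

**Mirror symmetry.** Reflecting the world across the course axis and
swapping the sensor channels maps the controller onto itself, and all
geometry is implemented reflection-exactly (y-negation). The weight,
learning-rate, and reward trajectories of mirrored runs swap *bitwise*; the
robot paths reflect exactly up to the one-control-period skew in turn onset
described above (sub-centimeter path differences in the mirrored trials).

## What the synthetic environment does not capture

Single-ray sensors instead of physical sonar cones; rectangular obstacles;
noiseless kinematics without wheel slip, motor lag, or braking distance;
instantaneous repositioning between trials; a fixed control period with no
communication jitter. Passing tests show that the learning rule and
architecture produce the claimed closed-loop behaviors under these idealized
conditions; they do not certify performance on physical hardware, where
drive calibration and sensor noise would dominate. The burst-onset margin
(baseline weight 1.000 vs onset 1.020) is deliberate but narrow: real-world
weight jitter of a few percent would require retuning the onset target.

## Numerical conventions

Band edges are inclusive for "straight". Tangent disc/rectangle contact
counts as a collision. Readings at exactly the clip boundaries take the
boundary values. The rate estimator counts spikes in a half-open window
(t − W, t]. The brake's `stop_active` flag looks back one control period.
Degenerate inputs (non-finite currents, negative distances, dt ≤ 0) are
rejected with `ValueError`s naming the offending quantity.
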