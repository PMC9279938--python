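"""Architecture, encoding, decoding, calibration contracts, and the
dopaminergic gating of the ten-neuron controller."""

import pytest

from snnbot.network import (
    Command,
    DecisionBands,
    EncoderParams,
    NetworkRuntime,
    NetworkSpec,
    build_network,
    decode_action,
    encode_distance,
    estimate_rate,
    encoder_rate,
    network_step,
)


class TestEncoding:
    def test_current_map_values(self):
        ep = EncoderParams()
        I_l, I_r = encode_distance(ep, 30.0, 15.0)
        assert I_l == pytest.approx(10.0 * 0.075)
        assert I_r == pytest.approx(10.0 * 0.15)

    def test_clipping_beyond_range(self):
        ep = EncoderParams()
        far, _ = encode_distance(ep, 50.0, 30.0)
        near, _ = encode_distance(ep, 5.0, 30.0)
        assert far == pytest.approx(10.0 * 0.075)
        assert near == pytest.approx(10.0 * 0.15)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            encode_distance(EncoderParams(), -1.0, 20.0)

    def test_operating_point_rates(self, calibrated_spec):
        assert encoder_rate(calibrated_spec, 30.0) == pytest.approx(25.0, rel=0.1)
        assert encoder_rate(calibrated_spec, 15.0) == pytest.approx(50.0, rel=0.1)


class TestArchitecture:
    def test_unit_counts(self):
        spec = build_network()
        assert len(spec.neuron_names) == 10
        assert set(spec.plastic_synapses) == {"w12", "w34"}
        assert set(spec.reward_channels) == {"R1", "R2"}

    def test_channel_wiring(self):
        spec = build_network()
        assert spec.reward_channels["R2"] == {
            "sensor": "Left", "relay": "N4", "synapse": "w34"}
        assert spec.reward_channels["R1"] == {
            "sensor": "Right", "relay": "N2", "synapse": "w12"}

    def test_mirror_reflection_maps_architecture_onto_itself(self):
        spec = build_network()
        swap = {"Left": "Right", "Right": "Left", "N1": "N3", "N3": "N1",
                "N2": "N4", "N4": "N2", "R1": "R2", "R2": "R1",
                "Out": "Out", "Stop": "Stop"}
        mirrored_plastic = {
            tuple(swap[n] for n in pair) for pair in spec.plastic_synapses.values()
        }
        assert mirrored_plastic == set(spec.plastic_synapses.values())
        mirrored_channels = {
            (swap[ch], swap[v["sensor"]], swap[v["relay"]])
            for ch, v in spec.reward_channels.items()
        }
        assert mirrored_channels == {
            (ch, v["sensor"], v["relay"]) for ch, v in spec.reward_channels.items()
        }

    def test_invalid_spec_rejected(self):
        spec = build_network()
        spec.tau_s = -1.0
        with pytest.raises(ValueError):
            spec.validate()


class TestDecoding:
    def test_rate_estimator(self):
        spikes = [i * 83.0 for i in range(1, 13)]
        assert estimate_rate(spikes, 1000.0, 1000.0) == pytest.approx(12.0)
        assert estimate_rate([], 1000.0, 1000.0) == 0.0

    def test_rate_estimator_periodic_edge_effect(self):
        spikes = [i * 40.0 for i in range(200)]
        for t in (1000.0, 1234.0, 5000.0):
            assert abs(estimate_rate(spikes, t, 1000.0) - 25.0) <= 1.0

    @pytest.mark.parametrize("rate,stop,want", [
        (12.0, False, Command.STRAIGHT),
        (20.0, False, Command.LEFT),
        (5.0, False, Command.RIGHT),
        (8.0, False, Command.STRAIGHT),   # band edges are inclusive
        (18.0, False, Command.STRAIGHT),
        (25.0, True, Command.STOP),       # the brake dominates any rate
        (0.0, True, Command.STOP),
    ])
    def test_band_rules(self, rate, stop, want):
        assert decode_action(rate, stop, DecisionBands()) is want


class TestCalibratedContracts:
    def test_baseline_silence_and_midband_rate(self, calibrated_spec):
        rt = NetworkRuntime(calibrated_spec)
        rel1, rel2, n_out = rt.run(100000, 30.0, 30.0)
        assert rel1 == 0 and rel2 == 0
        assert abs(n_out / 10.0 - 12.0) <= 0.5
        assert rt.syn12.w == pytest.approx(1.0, abs=1e-9)
        assert not rt.stop_spikes

    def test_relay_follows_pacemaker_at_baseline(self, calibrated_spec):
        rt = NetworkRuntime(calibrated_spec)
        rt.run(40000, 30.0, 30.0)
        assert rt.spike_counts["N1"] == rt.spike_counts["N2"]
        assert abs(rt.spike_counts["N1"] / 4.0 - 25.0) <= 0.5

    def test_left_proximity_engages_left_channel_only(self, calibrated_spec):
        rt = NetworkRuntime(calibrated_spec)
        rt.run(80000, 15.0, 30.0)
        assert rt.spike_counts["R2"] > 0
        assert rt.spike_counts["R1"] == 0
        assert rt.syn34.w > 1.01
        assert rt.syn12.w == pytest.approx(1.0, abs=1e-9)
        assert rt.syn34.gamma > calibrated_spec.plasticity.gamma0

    def test_left_proximity_drives_out_below_band(self, calibrated_spec):
        rt = NetworkRuntime(calibrated_spec)
        for _ in range(100):
            sample = rt.run_control_period(15.0, 30.0)
        assert sample.out_rate < calibrated_spec.bands.low_hz

    def test_right_proximity_drives_out_above_band(self, calibrated_spec):
        rt = NetworkRuntime(calibrated_spec)
        for _ in range(100):
            sample = rt.run_control_period(30.0, 15.0)
        assert sample.out_rate > calibrated_spec.bands.high_hz

    def test_gate_needs_conjunction_not_sensor_alone(self, calibrated_spec):
        """One dopaminergic channel in isolation: sensor proximity alone and
        relay pulses alone both stay subthreshold; their coincidence
        releases."""
        from snnbot.neuro_core import NeuronParams, NeuronState, SynapseParams, SynapseState
        from snnbot.network import dopamine_gate_step, encode_distance
        from snnbot.plasticity import RewardState

        spec = calibrated_spec
        I_near, _ = encode_distance(spec.encoder, spec.encoder.d_min, 30.0)
        sense_near = spec.cal.g_sense * I_near

        def run_channel(sensor_drive, relay_period_steps, n_steps):
            np_, ns = NeuronParams.leaky(), NeuronState()
            sp = SynapseParams(tau_s=spec.targets.gate_pulse_tau_s)
            ss = SynapseState()
            rw = RewardState(tau_r=spec.tau_r, C_r=spec.C_r)
            releases = 0
            for k in range(1, n_steps + 1):
                relay = relay_period_steps is not None and k % relay_period_steps == 0
                releases += dopamine_gate_step(
                    np_, ns, sp, ss, rw, sensor_drive, relay,
                    spec.cal.g_pulse, k * 0.1, 0.1,
                )
            return releases

        assert run_channel(sense_near, None, 50000) == 0       # sensor alone
        assert run_channel(0.0, 400, 50000) == 0               # relay alone
        assert run_channel(sense_near, 400, 2000) >= 1         # conjunction

    def test_gate_releases_quickly_under_proximity(self, calibrated_spec):
        rt = NetworkRuntime(calibrated_spec)
        rel1, rel2, _ = rt.run(2000, 15.0, 30.0)
        assert rel2 >= 1

    def test_brake_contracts(self, calibrated_spec):
        rt = NetworkRuntime(calibrated_spec)
        rt.plastic_enabled = False
        rt.run(50000, 15.0, 30.0)
        assert not rt.stop_spikes  # unilateral 50 Hz never brakes
        rt2 = NetworkRuntime(calibrated_spec)
        rt2.plastic_enabled = False
        rt2.run(5000, 15.0, 15.0)
        assert rt2.stop_spikes  # bilateral proximity brakes within 500 ms

    def test_learning_rate_persists_after_weight_relaxes(self, calibrated_spec):
        rt = NetworkRuntime(calibrated_spec)
        rt.run(60000, 15.0, 30.0)
        rt.run(20000, 30.0, 30.0)  # reward variable flushes to zero
        gamma_after = rt.syn34.gamma
        rt.run(150000, 30.0, 30.0)
        assert rt.syn34.w == pytest.approx(1.0, abs=2e-3)
        assert rt.syn34.gamma == gamma_after  # no reward, no γ change

    def test_open_loop_mirror_swap_is_exact(self, calibrated_spec):
        """Swapping the sensor streams swaps the weight, learning-rate, and
        reward trajectories bitwise (identical arithmetic on mirrored
        wiring)."""
        a = NetworkRuntime(calibrated_spec)
        b = NetworkRuntime(calibrated_spec)
        seq = [(30.0, 30.0)] * 10 + [(18.0, 30.0)] * 30 + [(15.0, 30.0)] * 30 \
            + [(24.0, 30.0)] * 20 + [(30.0, 30.0)] * 20
        for d_l, d_r in seq:
            sa = a.run_control_period(d_l, d_r)
            sb = b.run_control_period(d_r, d_l)
            assert sa.w34 == sb.w12 and sa.w12 == sb.w34
            assert sa.gamma34 == sb.gamma12 and sa.gamma12 == sb.gamma34
            assert sa.r2 == sb.r1 and sa.r1 == sb.r2

    def test_network_step_single_dt(self, calibrated_spec):
        rt = NetworkRuntime(calibrated_spec)
        rt, sample = network_step(calibrated_spec, rt, 30.0, 30.0)
        assert sample.t == pytest.approx(calibrated_spec.dt)
        with pytest.raises(ValueError):
            network_step(calibrated_spec, rt, 30.0, 30.0, dt=1.0)


def test_runtime_requires_calibration():
    with pytest.raises(ValueError):
        NetworkRuntime(NetworkSpec())
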