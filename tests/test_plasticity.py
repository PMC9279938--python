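"""Learning-rule checks: trace/pair equivalence, eligibility and reward
kinetics, the forgetting term, and the adaptive learning rate."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snnbot.plasticity import (
    PlasticityParams,
    PlasticSynapseState,
    RewardState,
    brute_force_stdp,
    classic_rstdp_step,
    improved_rule_step,
    stdp_increment,
    update_eligibility,
    update_reward,
    update_traces,
)

DT = 0.1


def run_trace_stdp(pre_steps, post_steps, p, n_steps, dt=DT):
    """Accumulate stdp_increment over gridded spike trains (engine order:
    decay, evaluate on pre-jump traces, jump)."""
    s = PlasticSynapseState()
    pre, post = set(pre_steps), set(post_steps)
    total = 0.0
    for k in range(1, n_steps + 1):
        a, b = k in pre, k in post
        s.x *= math.exp(-dt / p.tau_plus)
        s.y *= math.exp(-dt / p.tau_minus)
        total += stdp_increment(p, s, a, b)
        if a:
            s.x += 1.0
        if b:
            s.y += 1.0
    return total


class TestTraces:
    def test_decay_and_unit_jump(self):
        p, s = PlasticityParams(), PlasticSynapseState()
        update_traces(p, s, True, False, DT)
        assert s.x == 1.0 and s.y == 0.0
        for _ in range(100):
            update_traces(p, s, False, False, DT)
        assert s.x == pytest.approx(math.exp(-1.0), rel=1e-9)

    def test_superposition_of_two_spikes(self):
        p, s = PlasticityParams(), PlasticSynapseState()
        update_traces(p, s, True, False, DT)
        for _ in range(99):
            update_traces(p, s, False, False, DT)
        update_traces(p, s, True, False, DT)
        assert s.x == pytest.approx(1.0 + math.exp(-1.0), rel=1e-9)


class TestPairRule:
    def test_single_pair_potentiation(self):
        # pre at 0, post 10 ms later: increment A_plus·exp(−10/τ₊) = 1/e
        p = PlasticityParams()
        total = run_trace_stdp([10], [110], p, 200)
        assert total == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_single_pair_depression(self):
        p = PlasticityParams()
        total = run_trace_stdp([110], [10], p, 200)
        assert total == pytest.approx(-math.exp(-1.0), abs=1e-12)

    def test_simultaneous_pair_contributes_nothing(self):
        p = PlasticityParams()
        assert run_trace_stdp([50], [50], p, 100) == 0.0

    def test_matches_all_pairs_oracle_on_random_trains(self):
        """The recursive trace form equals the explicit all-pairs sum."""
        rng = random.Random(7)
        p = PlasticityParams()
        for _ in range(100):
            pre = sorted(rng.sample(range(1, 5000), 50))
            post = sorted(rng.sample(range(1, 5000), 50))
            got = run_trace_stdp(pre, post, p, 5000)
            want = brute_force_stdp([k * DT for k in pre], [k * DT for k in post], p)
            assert got == pytest.approx(want, abs=1e-9)

    def test_brute_force_edge_cases(self):
        p = PlasticityParams()
        assert brute_force_stdp([], [], p) == 0.0
        assert brute_force_stdp([0.0], [10.0], p) == pytest.approx(math.exp(-1.0))


class TestEligibilityAndReward:
    def test_eligibility_closed_form(self):
        p, s = PlasticityParams(), PlasticSynapseState()
        update_eligibility(p, s, 1.0, DT)
        for _ in range(100):
            update_eligibility(p, s, 0.0, DT)
        assert s.c == pytest.approx(math.exp(-1.0), rel=1e-9)

    def test_eligibility_superposition(self):
        p, s = PlasticityParams(), PlasticSynapseState()
        update_eligibility(p, s, 1.0, DT)
        for _ in range(99):
            update_eligibility(p, s, 0.0, DT)
        update_eligibility(p, s, 1.0, DT)
        assert s.c == pytest.approx(1.0 + math.exp(-1.0), rel=1e-9)

    def test_reward_release_and_decay(self):
        rs = RewardState()
        update_reward(rs, 1, DT)
        assert rs.r == pytest.approx(0.07)
        for _ in range(20):
            update_reward(rs, 0, DT)
        assert rs.r == pytest.approx(0.07 * math.exp(-1.0), rel=1e-9)

    def test_simultaneous_releases_add_linearly(self):
        rs = RewardState()
        update_reward(rs, 3, DT)
        assert rs.r == pytest.approx(0.21)

    def test_negative_release_count_rejected(self):
        with pytest.raises(ValueError):
            update_reward(RewardState(), -1, DT)


class TestWeightRules:
    def test_classic_rule_zero_reward_freezes_weight(self):
        s = PlasticSynapseState(w=1.5, c=2.0)
        classic_rstdp_step(s, 0.0, DT)
        assert s.w == 1.5

    def test_classic_rule_integrates_linearly(self):
        s = PlasticSynapseState(w=1.0, c=1.0, gamma=0.01)
        for _ in range(1000):
            classic_rstdp_step(s, 0.5, DT)
        assert s.w == pytest.approx(1.0 + 0.01 * 0.5 * 1.0 * 100.0, rel=1e-9)

    def test_forgetting_relaxation_and_frozen_gamma(self):
        # with no reward the weight relaxes to w0 exponentially; γ is untouched
        p = PlasticityParams()
        s = PlasticSynapseState(w=2.0, gamma=p.gamma0)
        n = int(round(p.tau_w / DT))
        for _ in range(n):
            improved_rule_step(p, s, 0.0, DT)
        assert s.w == pytest.approx(1.0 + math.exp(-1.0), rel=2e-3)
        assert s.gamma == p.gamma0

    def test_gamma_grows_linearly_under_constant_drive(self):
        p = PlasticityParams()
        s = PlasticSynapseState(w=1.0, c=1.0, gamma=p.gamma0)
        for _ in range(10000):
            s.c = 1.0
            improved_rule_step(p, s, 0.5, DT)
        assert s.gamma == pytest.approx(p.gamma0 + p.l * 0.5 * 1000.0, rel=1e-6)

    def test_degenerates_to_classic_rule(self):
        # with 1/τ_w = 0 and l = 0 both rules produce the same trajectory
        p = PlasticityParams(tau_w=1e30, l=0.0)
        a = PlasticSynapseState(w=1.0, c=0.8, gamma=0.02)
        b = PlasticSynapseState(w=1.0, c=0.8, gamma=0.02)
        for k in range(2000):
            r = 0.05 * (1 + math.sin(k / 50.0))
            improved_rule_step(p, a, r, DT)
            classic_rstdp_step(b, r, DT)
            assert a.w == pytest.approx(b.w, abs=1e-12)

    def test_fixed_point_matches_fine_integration(self):
        """Under constant r·c the weight settles at w0 + τ_w·γ·r·c, verified
        against brute-force integration at a 100× finer step."""
        p = PlasticityParams(l=0.0)
        rc = 0.004
        s = PlasticSynapseState(w=1.0, c=1.0, gamma=p.gamma0)
        for _ in range(int(8 * p.tau_w / DT)):
            s.c = 1.0
            improved_rule_step(p, s, rc, DT)
        expected = 1.0 + p.tau_w * p.gamma0 * rc
        assert s.w == pytest.approx(expected, rel=1e-3)
        w, fine = 1.0, DT / 100.0
        for _ in range(int(8 * p.tau_w / fine)):
            w += p.gamma0 * rc * fine - (w - 1.0) / p.tau_w * fine
        assert s.w == pytest.approx(w, rel=1e-3)

    def test_weight_clamped_at_zero(self):
        p = PlasticityParams(tau_w=1.0)
        s = PlasticSynapseState(w=0.0001, c=-5.0, gamma=1.0)
        improved_rule_step(p, s, 10.0, DT)
        assert s.w == 0.0


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    r_seq=st.lists(st.floats(0.0, 0.2), min_size=10, max_size=200),
    c0=st.floats(0.0, 3.0),
)
def test_monotone_consolidation(r_seq, c0):
    """Non-negative reward × eligibility never decreases the learning rate,
    and with zero reward |w − w0| shrinks every step."""
    p = PlasticityParams()
    s = PlasticSynapseState(w=1.7, c=c0, gamma=p.gamma0)
    last_gamma = s.gamma
    for r in r_seq:
        update_eligibility(p, s, 0.0, DT)
        improved_rule_step(p, s, r, DT)
        assert s.gamma >= last_gamma
        assert math.isfinite(s.w) and math.isfinite(s.gamma)
        last_gamma = s.gamma
    gap = abs(s.w - 1.0)
    for _ in range(50):
        improved_rule_step(p, s, 0.0, DT)
        new_gap = abs(s.w - 1.0)
        assert new_gap <= gap
        gap = new_gap
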