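import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psirt1 import (
    SequenceParams,
    TissueState,
    apparent_relaxation,
    look_locker_signal,
    propagate_kernel,
    pulse_by_pulse_trajectory,
    relax_toward,
    steady_state_kernel,
)
from psirt1.relaxometry import apparent_relaxation_arrays, steady_state_m_a

from conftest import discrete_readout_steady_state


class TestSequenceParams:
    def test_t_acq_is_tfe_times_tr(self, protocol_seq):
        assert protocol_seq.t_acq_ms == pytest.approx(216.2)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(rr_ms=-1),
            dict(tr_ms=0),
            dict(flip_deg=95.0),
            dict(flip_deg=-1.0),
            dict(inversion_deg=90.0),
            dict(inversion_deg=181.0),
            dict(tfe_factor=0),
            dict(kernel_rr=3),
            dict(t_inv_ms=-5.0),
            dict(t_inv_ms=800.0),  # readout would spill past the RR interval
        ],
    )
    def test_invalid_parameters_raise(self, kwargs):
        base = dict(rr_ms=1000.0, t_inv_ms=300.0, tr_ms=9.4, flip_deg=18.0, tfe_factor=23)
        base.update(kwargs)
        with pytest.raises(ValueError):
            SequenceParams(**base)

    def test_look_locker_readout_may_fill_the_rr(self):
        SequenceParams(1000.0, 0.0, 25.0, 15.0, 40, kernel_rr=1)  # 40 * 25 = RR


class TestApparentRelaxation:
    def test_zero_flip_is_identity(self, tissue_400, protocol_seq):
        ar = apparent_relaxation(tissue_400, protocol_seq.replace(flip_deg=0.0))
        assert ar.t1_star_ms == pytest.approx(400.0)
        assert ar.m0_star == pytest.approx(1.0)

    def test_t1_star_at_illustration_parameters(self, tissue_400, fig1_seq):
        # 1/t1* = 1/400 - ln(cos 15deg)/10 -> 167.6 ms
        ar = apparent_relaxation(tissue_400, fig1_seq)
        assert ar.t1_star_ms == pytest.approx(167.6, abs=0.1)

    def test_t1_star_at_invivo_protocol(self, protocol_seq):
        ar = apparent_relaxation(TissueState(300.0), protocol_seq)
        assert ar.t1_star_ms == pytest.approx(115.0, abs=0.5)

    def test_m0_star_matches_pulse_recursion_oracle(self, fig1_seq):
        # saturated steady state must agree with brute-force pulse iteration
        # to well under 0.5%
        ar = apparent_relaxation(TissueState(400.0), fig1_seq)
        oracle = discrete_readout_steady_state(400.0, 1.0, fig1_seq.tr_ms, fig1_seq.flip_deg)
        assert ar.m0_star == pytest.approx(oracle, rel=1e-9)

    def test_t1_star_decay_matches_pulse_recursion_oracle(self, fig1_seq):
        # the decay rate toward the saturated state, measured from the pulse
        # recursion, must equal 1/t1*
        t1, tr = 400.0, fig1_seq.tr_ms
        e, cosa = np.exp(-tr / t1), np.cos(np.radians(fig1_seq.flip_deg))
        m_ss = discrete_readout_steady_state(t1, 1.0, tr, fig1_seq.flip_deg)
        m = -1.0
        deviations = []
        for _ in range(3):
            m = m * cosa * e + 1.0 - e
            deviations.append(m - m_ss)
        rate = -np.log(deviations[1] / deviations[0]) / tr
        ar = apparent_relaxation(TissueState(t1), fig1_seq)
        assert 1.0 / ar.t1_star_ms == pytest.approx(rate, rel=1e-9)

    def test_monotone_saturation_in_flip_angle(self, protocol_seq):
        flips = np.arange(1.0, 90.0, 4.0)
        t1s = []
        m0s = []
        for f in flips:
            ar = apparent_relaxation(TissueState(400.0), protocol_seq.replace(flip_deg=f))
            t1s.append(ar.t1_star_ms)
            m0s.append(ar.m0_star)
        assert np.all(np.diff(t1s) < 0)
        assert np.all(np.diff(m0s) < 0)
        assert all(0 < t < 400.0 for t in t1s)
        assert all(0 < m < 1.0 for m in m0s)


class TestRelaxToward:
    def test_zero_duration_returns_start(self):
        assert relax_toward(-0.3, 1.0, 0.0, 400.0) == pytest.approx(-0.3)

    def test_long_duration_returns_target(self):
        assert relax_toward(-1.0, 1.0, 1e9, 400.0) == pytest.approx(1.0)

    def test_one_tau(self):
        # -1 -> 1 over one time constant: 1 - 2/e
        assert relax_toward(-1.0, 1.0, 400.0, 400.0) == pytest.approx(1.0 - 2.0 / np.e)

    @given(
        m_start=st.floats(-2, 2),
        m_target=st.floats(-2, 2),
        d1=st.floats(0, 2000),
        d2=st.floats(0, 2000),
        tau=st.floats(1, 5000),
    )
    @settings(max_examples=50, deadline=None)
    def test_semigroup_property(self, m_start, m_target, d1, d2, tau):
        # relaxing d1 then d2 equals relaxing d1 + d2
        two_step = relax_toward(relax_toward(m_start, m_target, d1, tau), m_target, d2, tau)
        one_step = relax_toward(m_start, m_target, d1 + d2, tau)
        assert two_step == pytest.approx(one_step, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            relax_toward(0.0, 1.0, 10.0, 0.0)
        with pytest.raises(ValueError):
            relax_toward(0.0, 1.0, -1.0, 400.0)


class TestPropagateKernel:
    def test_pure_ir_full_recovery(self):
        seq = SequenceParams(1e6, 300.0, 9.4, 0.0, 23)
        kernel = propagate_kernel(TissueState(400.0), seq, m_a=-1.0)
        assert kernel.m_f == pytest.approx(1.0, abs=1e-12)

    def test_instant_recovery_for_tiny_t1(self, protocol_seq):
        kernel = propagate_kernel(TissueState(1e-6), protocol_seq, m_a=-1.0)
        assert kernel.m_b == pytest.approx(1.0, abs=1e-9)
        assert kernel.m_d == pytest.approx(1.0, abs=1e-9)

    def test_matches_pulse_by_pulse_oracle_at_illustration_settings(self, fig1_seq):
        tissue = TissueState(400.0)
        ss = steady_state_kernel(tissue, fig1_seq)
        oracle = pulse_by_pulse_trajectory(tissue, fig1_seq, [fig1_seq.rr_ms] * 80)[-1]
        assert np.max(np.abs(ss.as_array() - oracle.as_array())) < 1e-6

    def test_requires_psir_kernel(self, ll_seq):
        with pytest.raises(ValueError):
            propagate_kernel(TissueState(400.0), ll_seq, m_a=-1.0)


class TestSteadyState:
    def test_fixed_point_property(self, tissue_400, protocol_seq):
        ss = steady_state_kernel(tissue_400, protocol_seq)
        again = propagate_kernel(tissue_400, protocol_seq, ss.m_a)
        assert again.m_f == pytest.approx(-ss.m_a, abs=1e-10)

    def test_single_shot_limit_is_minus_m0(self, tissue_400, protocol_seq):
        ss = steady_state_kernel(tissue_400, protocol_seq.replace(rr_ms=1e7))
        assert ss.m_a == pytest.approx(-1.0, abs=1e-9)

    @pytest.mark.parametrize("t1", [100.0, 400.0, 1200.0])
    @pytest.mark.parametrize("hr", [60.0, 90.0])
    def test_multi_shot_saturation(self, protocol_seq, t1, hr):
        seq = protocol_seq.replace(rr_ms=60000.0 / hr)
        ss = steady_state_kernel(TissueState(t1), seq)
        assert abs(ss.m_a) < 1.0
        assert ss.m_a < 0

    def test_closed_form_and_iteration_agree(self, tissue_400, protocol_seq):
        a = steady_state_kernel(tissue_400, protocol_seq, method="closed_form")
        b = steady_state_kernel(tissue_400, protocol_seq, method="iterate")
        assert np.allclose(a.as_array(), b.as_array(), atol=1e-12)

    @pytest.mark.parametrize("t1", [150.0, 400.0, 900.0])
    def test_each_segment_moves_toward_its_target(self, protocol_seq, t1):
        # free segments move toward m0, readout segments toward m0_star;
        # a segment entering above its target relaxes down, below it up
        from psirt1.relaxometry import _kernel_segments

        tissue = TissueState(t1)
        ss = steady_state_kernel(tissue, protocol_seq)
        values = ss.as_array()
        for i, (_, target, _) in enumerate(_kernel_segments(t1, 1.0, protocol_seq)):
            start, end = values[i], values[i + 1]
            assert abs(end - float(target)) <= abs(start - float(target))
            if start != end:
                assert np.sign(end - start) == np.sign(float(target) - start)
        # the second readout start always sees more recovery than the first
        assert ss.m_d > ss.m_b

    @pytest.mark.parametrize("t1", [200.0, 400.0, 800.0])
    @pytest.mark.parametrize("flip", [5.0, 15.0, 25.0])
    @pytest.mark.parametrize("hr", [60.0, 90.0])
    def test_oracle_equivalence_grid(self, protocol_seq, t1, flip, hr):
        seq = protocol_seq.replace(rr_ms=60000.0 / hr, flip_deg=flip)
        tissue = TissueState(t1)
        ss = steady_state_kernel(tissue, seq)
        oracle = pulse_by_pulse_trajectory(tissue, seq, [seq.rr_ms] * 80)[-1]
        assert np.max(np.abs(ss.as_array() - oracle.as_array())) < 1e-4

    @given(c=st.floats(0.01, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_linearity_in_m0(self, c):
        seq = SequenceParams(1000.0, 300.0, 9.4, 18.0, 23)
        base = steady_state_kernel(TissueState(400.0, 1.0), seq).as_array()
        scaled = steady_state_kernel(TissueState(400.0, c), seq).as_array()
        assert np.allclose(scaled, c * base, rtol=1e-12)


class TestLookLocker:
    def test_single_shot_limit(self, ll_seq):
        tissue = TissueState(500.0)
        seq = ll_seq.replace(rr_ms=1e6, tfe_factor=40000)
        t1_star, m0_star = apparent_relaxation_arrays(500.0, 1.0, seq)
        t = 200.0
        expected = m0_star * (1.0 - 2.0 * np.exp(-t / t1_star))
        assert look_locker_signal(t, tissue, seq) == pytest.approx(float(expected), rel=1e-9)

    def test_negative_at_t0(self, ll_seq):
        tissue = TissueState(500.0)
        t1_star, m0_star = apparent_relaxation_arrays(500.0, 1.0, ll_seq)
        e = np.exp(-ll_seq.rr_ms / t1_star)
        expected = m0_star * (e - 1.0) / (1.0 + e)
        value = look_locker_signal(0.0, tissue, ll_seq)
        assert value < 0
        assert value == pytest.approx(float(expected), rel=1e-12)

    def test_reduces_to_general_kernel_with_full_rr_readout(self, ll_seq):
        # t_inv = 0 and a readout filling the RR make the general single-RR
        # kernel identical to the continuous Look-Locker steady state
        tissue = TissueState(420.0)
        m_a = float(steady_state_m_a(tissue.t1_ms, tissue.m0, ll_seq))
        t1_star, m0_star = apparent_relaxation_arrays(tissue.t1_ms, tissue.m0, ll_seq)
        times = np.linspace(0.0, ll_seq.rr_ms - 1.0, 57)
        from_kernel = m0_star + (m_a - m0_star) * np.exp(-times / t1_star)
        direct = look_locker_signal(times, tissue, ll_seq)
        assert np.max(np.abs(from_kernel - direct)) < 1e-8

    def test_rejects_psir_kernel_and_bad_times(self, protocol_seq, ll_seq):
        with pytest.raises(ValueError):
            look_locker_signal(100.0, TissueState(400.0), protocol_seq)
        with pytest.raises(ValueError):
            look_locker_signal(ll_seq.rr_ms, TissueState(400.0), ll_seq)
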