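"""Time-domain interface-circuit behaviour."""

import numpy as np
import pytest
from scipy.optimize import brentq

from cfesim.cpe_network import RCNetwork, network_impedance, synthesize_network, \
    CPEInterfaceParams
from cfesim.interface_circuit import (FaradaicParams, PulseSpec, make_pulse_train,
                                      faradaic_current, simulate_interface,
                                      relative_loss)
from cfesim.errors import ValidationError


class TestPulseTrain:
    def test_plateau_and_midramp_values(self):
        spec = PulseSpec(amplitude=20.0, width=50e-3,
                         rise_time=10e-6, fall_time=10e-6)
        wave = make_pulse_train(spec)
        assert wave(25e-3) == pytest.approx(20.0)
        assert wave(5e-6) == pytest.approx(10.0)
        assert wave(-1e-3) == 0.0

    def test_five_pulse_train_disjoint_support(self):
        spec = PulseSpec(amplitude=20.0, width=50e-3, rise_time=10e-6,
                         fall_time=10e-6, n_pulses=5, inter_pulse_gap=50e-3)
        wave = make_pulse_train(spec)
        t = np.linspace(0, spec.total_duration + 40e-3, 200001)
        on = wave(t) > 0
        # count contiguous on-intervals
        starts = np.sum((~on[:-1]) & on[1:]) + int(on[0])
        assert starts == 5
        gap_mid = spec.width + spec.fall_time + 0.5 * spec.inter_pulse_gap
        assert wave(gap_mid) == 0.0

    def test_invalid_times_rejected(self):
        with pytest.raises(ValidationError):
            PulseSpec(width=-1.0)
        with pytest.raises(ValidationError):
            PulseSpec(width=5e-6, rise_time=10e-6)


class TestFaradaicBranch:
    def test_zero_voltage_zero_current(self):
        assert faradaic_current(0.0, 0.0, FaradaicParams()) == 0.0

    def test_odd_symmetry_at_zero_charge(self):
        p = FaradaicParams()
        for v in (0.01, 0.5, 5.0, 20.0):
            assert faradaic_current(-v, 0.0, p) == -faradaic_current(v, 0.0, p)

    def test_subthreshold_linearization_bound(self):
        p = FaradaicParams()
        v = 1e-4 * p.n_ideality * p.V_T
        i = faradaic_current(v, 0.0, p)
        assert 0 < i <= p.I_s * v / (p.n_ideality * p.V_T) * (1 + 1e-6)

    @pytest.mark.parametrize("v", [2.0, 5.0, 15.0])
    def test_against_scalar_root_find_oracle(self, v):
        p = FaradaicParams()
        for q in (0.0, 10.0 * p.q_0):
            M = p.memristance(q)
            a = p.n_ideality * p.V_T

            def g(i):
                return a * np.log1p(i / p.I_s) + M * i - v

            oracle = brentq(g, 0.0, v / M, xtol=1e-15, rtol=1e-14)
            assert faradaic_current(v, q, p) == pytest.approx(oracle, rel=1e-9)

    def test_current_grows_with_delivered_charge(self):
        p = FaradaicParams()
        assert faradaic_current(5.0, 10 * p.q_0, p) > faradaic_current(5.0, 0.0, p)

    def test_memristance_floor(self):
        p = FaradaicParams()
        assert p.memristance(1e6 * p.q_0) == p.M_min


class TestIntegrator:
    def test_single_branch_step_matches_closed_form(self):
        R1, C1, Rs, Rt, V0 = 1000.0, 1e-6, 300.0, 500.0, 5.0
        net = RCNetwork(R=[R1], C=[C1], center=0, f_lo=1, f_hi=10)
        pulse = PulseSpec(amplitude=V0, width=20e-3, rise_time=1e-9,
                          fall_time=1e-9)
        r = simulate_interface(net, Rs, None, Rt, pulse, dt_max=1e-6,
                               store_every=20)
        tau = C1 * (R1 + Rs + Rt)
        mask = (r.time > 1e-6) & (r.time < 20e-3)
        exact = V0 * (Rs + Rt) / (R1 + Rs + Rt) * np.exp(-r.time[mask] / tau)
        np.testing.assert_allclose(r.v_after_interface[mask], exact, rtol=1e-6)
        # tissue node is the R_tissue fraction of the same waveform
        np.testing.assert_allclose(r.v_tissue[mask], exact * Rt / (Rs + Rt),
                                   rtol=1e-6)

    @pytest.mark.parametrize("f0", [10.0, 100.0, 1000.0])
    def test_sinusoid_matches_frequency_domain_divider(self, reference_ladder, f0):
        params, net = reference_ladder
        Rt = 522.0
        w = 2 * np.pi * f0
        Zl = network_impedance(net, 0.0, f0)
        H = (params.R_s + Rt) / (Zl + params.R_s + Rt)
        A = 0.03
        # warm start on the phasor steady state, then check it is maintained
        vb0 = np.real(A * (Zl / (Zl + params.R_s + Rt))
                      * (1 / (1 + 1j * w * net.R * net.C)))
        r = simulate_interface(
            net, params.R_s, None, Rt,
            drive=lambda t: A * np.cos(w * np.asarray(t)),
            t_end=2.0 / f0, dt_max=min(1e-6, 1.0 / (2000.0 * f0)),
            initial_branch_voltages=vb0)
        X = np.column_stack([np.cos(w * r.time), np.sin(w * r.time)])
        c = np.linalg.lstsq(X, r.v_after_interface, rcond=None)[0]
        amp, phase = np.hypot(*c), np.arctan2(-c[1], c[0])
        assert amp / (A * abs(H)) == pytest.approx(1.0, abs=0.005)
        assert abs(np.degrees(phase - np.angle(H))) < 0.5

    def test_fixed_step_determinism_bit_identical(self, reference_ladder):
        params, net = reference_ladder
        pulse = PulseSpec(amplitude=20.0, width=2e-3, rise_time=10e-6,
                          fall_time=10e-6)
        a = simulate_interface(net, params.R_s, FaradaicParams(), 522.0, pulse,
                               dt_max=1e-6)
        b = simulate_interface(net, params.R_s, FaradaicParams(), 522.0, pulse,
                               dt_max=1e-6)
        assert np.array_equal(a.v_tissue, b.v_tissue)
        assert np.array_equal(a.q, b.q)

    def test_initial_state_and_energy_positivity(self, reference_ladder):
        params, net = reference_ladder
        pulse = PulseSpec(amplitude=20.0, width=2e-3, rise_time=10e-6,
                          fall_time=10e-6)
        r = simulate_interface(net, params.R_s, FaradaicParams(), 522.0, pulse,
                               dt_max=1e-6)
        assert r.time[0] == 0.0
        assert np.all(r.branch_voltages[0] == 0.0) and r.q[0] == 0.0
        # energy into the series resistances is non-negative
        assert np.all(r.i_total ** 2 * (params.R_s + 522.0) >= 0.0)
        assert np.all(np.diff(r.time) > 0)

    def test_charge_persists_across_pulses_by_default(self, reference_ladder):
        params, net = reference_ladder
        pulse = PulseSpec(amplitude=20.0, width=2e-3, rise_time=10e-6,
                          fall_time=10e-6, n_pulses=2, inter_pulse_gap=1e-3)
        r = simulate_interface(net, params.R_s, FaradaicParams(), 522.0, pulse,
                               dt_max=1e-6)
        q_end_p1 = r.at(pulse.width + pulse.fall_time)["q"]
        q_end_p2 = r.at(pulse.total_duration)["q"]
        assert q_end_p2 > q_end_p1 > 0
        r2 = simulate_interface(net, params.R_s, FaradaicParams(), 522.0, pulse,
                                dt_max=1e-6, reset_charge_between_pulses=True)
        assert r2.at(pulse.total_duration)["q"] < q_end_p2


@pytest.fixture(scope="module")
def responses(reference_ladder):
    """20 V / 50 ms pulse responses (10 us ramps) across loads, +- Faradaic."""
    params, net = reference_ladder
    pulse = PulseSpec(amplitude=20.0, width=50e-3, rise_time=10e-6,
                      fall_time=10e-6)
    out = {}
    for fa in (None, FaradaicParams()):
        for rt in (174.0, 522.0, 5000.0):
            out[(fa is not None, rt)] = simulate_interface(
                net, params.R_s, fa, rt, pulse, dt_max=1e-6,
                store_every=20)
    return pulse, out


class TestPulseResponseShape:
    """Contracts on the 20 V / 50 ms pulse response (10 us ramps)."""

    def test_onset_peak_plateau_and_termination(self, responses):
        pulse, out = responses
        r = out[(False, 522.0)]
        plateau = r.at(pulse.width)["v_out"]
        onset = np.max(r.v_out[r.time <= 5 * pulse.rise_time])
        assert onset > plateau > 0.0
        # termination transient: the interface discharges through the load
        tail = r.v_out[r.time > pulse.width + pulse.fall_time]
        assert tail.min() < -0.1 * plateau

    def test_faradaic_masks_the_cpe_peaks(self, responses):
        pulse, out = responses
        gap = {}
        for fa in (False, True):
            r = out[(fa, 522.0)]
            gap[fa] = np.max(r.v_out) - r.at(pulse.width)["v_out"]
        assert gap[True] < 0.2 * gap[False]

    def test_faradaic_raises_delivered_plateau(self, responses):
        pulse, out = responses
        for rt in (174.0, 522.0):
            v_dis = out[(False, rt)].at(pulse.width)["v_out"]
            v_en = out[(True, rt)].at(pulse.width)["v_out"]
            assert v_en > v_dis

    def test_steady_loss_decreases_with_tissue_resistance(self, responses):
        pulse, out = responses
        for fa in (False, True):
            losses = [relative_loss(out[(fa, rt)], 20.0)[1]
                      for rt in (174.0, 522.0, 5000.0)]
            assert losses[0] > losses[1] > losses[2]
            assert all(0.0 <= l <= 1.0 for l in losses)

    def test_peak_loss_within_unit_interval(self, responses):
        pulse, out = responses
        for key, r in out.items():
            pl, sl = relative_loss(r, 20.0)
            assert 0.0 <= pl <= 1.0 and 0.0 <= sl <= 1.0

    def test_relative_loss_requires_positive_applied(self, responses):
        _, out = responses
        with pytest.raises(ValidationError):
            relative_loss(out[(True, 522.0)], 0.0)
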