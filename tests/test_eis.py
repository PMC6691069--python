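"""EIS data model, synthesis and CPE fitting."""

import io

import numpy as np
import pytest

from cfesim.eis import (ImpedanceSpectrum, IdealCPEParams, NoiseModel,
                        ideal_cpe_impedance, theta_to_m, fit_cpe,
                        generate_synthetic_eis, read_eis_csv, write_eis_csv)
from cfesim.errors import FormatError, ValidationError

F_GRID = np.logspace(-1, 4, 41)


class TestSpectrumInvariants:
    def test_arrays_must_match_and_be_valid(self):
        with pytest.raises(ValidationError):
            ImpedanceSpectrum([1.0, 2.0], [10.0], [5.0, 5.0])
        with pytest.raises(ValidationError, match="frequency"):
            ImpedanceSpectrum([0.0, 1.0], [10.0, 10.0], [5.0, 5.0])
        with pytest.raises(ValidationError, match="ascending"):
            ImpedanceSpectrum([2.0, 1.0], [10.0, 10.0], [5.0, 5.0])
        with pytest.raises(ValidationError, match="magnitude"):
            ImpedanceSpectrum([1.0, 2.0], [10.0, -1.0], [5.0, 5.0])
        with pytest.raises(ValidationError, match=r"\[0, 90\]"):
            ImpedanceSpectrum([1.0, 2.0], [10.0, 10.0], [5.0, 95.0])

    def test_complex_impedance_uses_capacitive_sign(self):
        s = ImpedanceSpectrum([1.0], [100.0], [60.0])
        z = s.complex_impedance[0]
        assert z.imag < 0 and np.isclose(abs(z), 100.0)


class TestCsvIo:
    def _csv(self, text):
        return io.StringIO(text)

    def test_single_electrode_parse(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("frequency_hz,magnitude_ohm,phase_deg,electrode_id\n"
                     "10,100,60,e1\n1,1000,65,e1\n100,10,50,e1\n")
        spectra = read_eis_csv(p)
        assert len(spectra) == 1 and len(spectra[0]) == 3
        assert np.all(np.diff(spectra[0].frequencies) > 0)  # sorted on read

    def test_two_electrodes_grouped(self, tmp_path):
        p = tmp_path / "two.csv"
        p.write_text("frequency_hz,magnitude_ohm,phase_deg,electrode_id\n"
                     "1,100,60,e1\n10,50,55,e1\n1,200,62,e2\n10,80,58,e2\n")
        spectra = read_eis_csv(p)
        assert [s.electrode_id for s in spectra] == ["e1", "e2"]

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("frequency_hz,magnitude_ohm,electrode_id\n1,100,e1\n")
        with pytest.raises(FormatError, match="phase_deg"):
            read_eis_csv(p)

    def test_zero_frequency_is_validation_error(self, tmp_path):
        p = tmp_path / "zero.csv"
        p.write_text("frequency_hz,magnitude_ohm,phase_deg,electrode_id\n"
                     "0,100,60,e1\n1,90,61,e1\n")
        with pytest.raises(ValidationError):
            read_eis_csv(p)

    def test_round_trip_bit_comparable(self, tmp_path):
        s = generate_synthetic_eis(IdealCPEParams(0.7, 1e4, 300.0), F_GRID,
                                   NoiseModel(0.02, 1.0), seed=7)
        p = tmp_path / "rt.csv"
        write_eis_csv(p, [s])
        back = read_eis_csv(p)[0]
        np.testing.assert_allclose(back.frequencies, s.frequencies, rtol=1e-11)
        np.testing.assert_allclose(back.magnitudes, s.magnitudes, rtol=1e-11)
        np.testing.assert_allclose(back.phases, s.phases, rtol=1e-11, atol=1e-12)


class TestIdealCpe:
    def test_capacitor_limit_phase_90(self):
        p = IdealCPEParams(m=1.0 - 1e-9, K=1e6, R_s=0.0)
        z = ideal_cpe_impedance(p, np.array([1.0, 10.0, 100.0]))
        assert np.allclose(-np.degrees(np.angle(z)), 90.0, atol=1e-5)

    def test_resistor_limit_flat_magnitude(self):
        p = IdealCPEParams(m=1e-6, K=123.0, R_s=0.0)
        z = ideal_cpe_impedance(p, np.array([0.1, 10.0, 1e4]))
        assert np.allclose(abs(z), 123.0, rtol=1e-4)
        assert np.allclose(np.degrees(np.angle(z)), 0.0, atol=0.01)

    def test_phase_is_m_times_90_at_any_frequency(self):
        p = IdealCPEParams(m=0.7256, K=5e4, R_s=0.0)
        for f in (0.1, 12.0, 9000.0):
            assert -np.degrees(np.angle(ideal_cpe_impedance(p, f))) == \
                pytest.approx(65.304, abs=1e-3)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValidationError):
            ideal_cpe_impedance(IdealCPEParams(0.5, 1.0), 0.0)


@pytest.mark.parametrize("theta,expected", [(65.3, 65.3 / 90.0),
                                            (45.0, 0.5)])
def test_theta_to_m(theta, expected):
    assert theta_to_m(theta) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("theta", [0.0, 90.0, -5.0, 120.0])
def test_theta_to_m_domain(theta):
    with pytest.raises(ValidationError):
        theta_to_m(theta)


class TestGenerator:
    def test_zero_noise_equals_model(self):
        p = IdealCPEParams(0.7, 1e4, 300.0)
        s = generate_synthetic_eis(p, F_GRID)
        z = ideal_cpe_impedance(p, F_GRID)
        np.testing.assert_allclose(s.magnitudes, abs(z), rtol=1e-12)
        np.testing.assert_allclose(s.phases, -np.degrees(np.angle(z)), rtol=1e-12)

    def test_same_seed_identical(self):
        p = IdealCPEParams(0.7, 1e4, 300.0)
        a = generate_synthetic_eis(p, F_GRID, NoiseModel(0.05, 2.0), seed=3)
        b = generate_synthetic_eis(p, F_GRID, NoiseModel(0.05, 2.0), seed=3)
        assert np.array_equal(a.magnitudes, b.magnitudes)
        assert np.array_equal(a.phases, b.phases)

    def test_noise_moments_match_stated_sds(self):
        p = IdealCPEParams(0.7, 1e4, 300.0)
        z = ideal_cpe_impedance(p, F_GRID)
        rel, dphi = [], []
        for seed in range(200):
            s = generate_synthetic_eis(p, F_GRID, NoiseModel(0.02, 1.0), seed=seed)
            rel.append(s.magnitudes / abs(z) - 1.0)
            dphi.append(s.phases + np.degrees(np.angle(z)))
        assert np.std(np.concatenate(rel)) == pytest.approx(0.02, rel=0.05)
        assert np.std(np.concatenate(dphi)) == pytest.approx(1.0, rel=0.05)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            generate_synthetic_eis(IdealCPEParams(0.7, 1e4), [])


class TestFit:
    def test_noiseless_self_consistency(self):
        true = IdealCPEParams(m=0.7, K=1e4, R_s=300.0)
        params, diag = fit_cpe(generate_synthetic_eis(true, F_GRID))
        assert params.m == pytest.approx(true.m, abs=1e-6)
        assert params.K == pytest.approx(true.K, rel=1e-6)
        assert params.R_s == pytest.approx(true.R_s, rel=1e-6)
        assert diag.converged and not diag.m_at_bound

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_recovery_within_tolerance(self, seed):
        # tolerances established by a 60-seed Monte-Carlo (max |dm| = 0.006,
        # max relative R_s error = 1.5%); asserted at the stated envelope
        true = IdealCPEParams(m=0.7, K=1e4, R_s=300.0)
        s = generate_synthetic_eis(true, F_GRID, NoiseModel(0.02, 1.0), seed=seed)
        params, _ = fit_cpe(s)
        assert abs(params.m - true.m) <= 0.02
        assert abs(params.R_s / true.R_s - 1.0) <= 0.10

    def test_phase_ceiling_on_noiseless_data(self):
        true = IdealCPEParams(m=0.82, K=2e4, R_s=0.0)
        s = generate_synthetic_eis(true, F_GRID)
        params, _ = fit_cpe(s)
        assert params.m * 90.0 <= np.max(s.phases) + 0.1

    def test_pure_resistor_pins_m_and_flags(self):
        s = ImpedanceSpectrum(F_GRID, np.full(F_GRID.size, 500.0),
                              np.zeros(F_GRID.size), "res")
        params, diag = fit_cpe(s)
        assert diag.m_at_bound
        assert params.m < 0.01

    def test_narrow_band_rejected(self):
        s = generate_synthetic_eis(IdealCPEParams(0.7, 1e4),
                                   np.logspace(0, 0.5, 10))
        with pytest.raises(ValidationError, match="decades"):
            fit_cpe(s)

    def test_toml_export_has_interface_field_names(self):
        text = IdealCPEParams(0.7256, 5e4, 297.0).to_toml()
        assert "theta_cpe_deg" in text and "r_s_ohm" in text
        assert "65.3" in text
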