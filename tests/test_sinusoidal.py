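"""Complex-modulus extraction, work/power curves and tension measures."""

import numpy as np
import pytest

from flymech.sinusoidal import (FiberGeometry, LengthForceTrace,
                                ComplexModulusSpectrum, analysis_window,
                                extract_complex_modulus, measure_tension,
                                summarize_spectrum, sweep_spectrum,
                                work_and_power)
from conftest import sinusoid_trace, spectrum_from_model


class TestExtraction:
    def test_pure_spring_is_in_phase(self):
        tr = sinusoid_trace(1000.0, 0.0)
        est = extract_complex_modulus(tr)
        assert est.elastic == pytest.approx(1000.0, rel=1e-9)
        assert est.viscous == pytest.approx(0.0, abs=1e-6)

    def test_pure_damper_is_in_quadrature(self):
        tr = sinusoid_trace(0.0, 1000.0)
        est = extract_complex_modulus(tr)
        assert est.elastic == pytest.approx(0.0, abs=1e-6)
        assert est.viscous == pytest.approx(1000.0, rel=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_noisy_recovery_within_two_percent(self, seed):
        tr = sinusoid_trace(800.0, -300.0, noise_sd=0.01, seed=seed)
        est = extract_complex_modulus(tr)
        assert est.elastic == pytest.approx(800.0, rel=0.02)
        assert est.viscous == pytest.approx(-300.0, rel=0.02)

    def test_projection_equals_dft_bin(self):
        """On integer-cycle windows the least-squares projection coincides
        with the DFT coefficient at the drive frequency."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            e1, e2 = rng.uniform(-800, 800, size=2)
            f = rng.uniform(20, 400)
            tr = sinusoid_trace(e1, e2, frequency=f, n_cycles=8,
                                sample_rate=200 * f,
                                offset=rng.uniform(-2, 2))
            win = analysis_window(tr)
            t, s = tr.time[win][:-1], tr.stress[win][:-1]  # open interval
            w = 2 * np.pi * f
            z = 2.0 / t.size * np.sum(s * np.exp(-1j * w * t))
            # DFT convention: s ~ Re(z e^{iwt}) = Re(z) cos - Im(z) sin
            e1_dft, e2_dft = -z.imag / tr.amplitude, z.real / tr.amplitude
            est = extract_complex_modulus(tr)
            assert est.elastic == pytest.approx(e1_dft, abs=1e-6 * max(abs(e1), 1))
            assert est.viscous == pytest.approx(e2_dft, abs=1e-6 * max(abs(e2), 1))

    def test_amplitude_invariance_for_linear_fiber(self):
        lo = sinusoid_trace(650.0, -120.0, amplitude=0.000625)
        hi = sinusoid_trace(650.0, -120.0, amplitude=0.00125)
        est_lo, est_hi = extract_complex_modulus(lo), extract_complex_modulus(hi)
        assert est_lo.elastic == pytest.approx(est_hi.elastic, rel=0.005)
        assert est_lo.viscous == pytest.approx(est_hi.viscous, rel=0.005)

    def test_too_few_cycles_rejected(self):
        tr = sinusoid_trace(500.0, 0.0, n_cycles=3)
        with pytest.raises(ValueError, match="cycles"):
            extract_complex_modulus(tr)

    def test_harmonic_distortion_warns(self):
        tr = sinusoid_trace(500.0, 0.0)
        tr.strain = tr.strain + 0.5 * tr.amplitude * np.sin(
            2 * np.pi * 3 * tr.drive_frequency * tr.time)
        with pytest.warns(UserWarning, match="distortion"):
            extract_complex_modulus(tr)


class TestSweep:
    def test_single_trace_gives_one_point(self):
        spec = sweep_spectrum([sinusoid_trace(700.0, -100.0)])
        assert len(spec) == 1

    def test_unsorted_input_sorted_ascending(self):
        traces = [sinusoid_trace(500.0, -50.0, frequency=f)
                  for f in (200.0, 50.0, 120.0)]
        spec = sweep_spectrum(traces)
        assert list(spec.frequencies) == [50.0, 120.0, 200.0]

    def test_duplicate_frequencies_rejected(self):
        traces = [sinusoid_trace(500.0, 0.0, frequency=100.0)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            sweep_spectrum(traces)

    def test_mixed_amplitudes_rejected(self):
        traces = [sinusoid_trace(500.0, 0.0, frequency=100.0, amplitude=0.00125),
                  sinusoid_trace(500.0, 0.0, frequency=150.0, amplitude=0.0025)]
        with pytest.raises(ValueError, match="amplitude"):
            sweep_spectrum(traces)

    def test_forward_model_round_trip(self, control_model):
        from flymech.synthetic import SyntheticProtocol, gen_linear_trace
        freqs = np.logspace(np.log10(5), np.log10(650), 12)
        traces = [gen_linear_trace(
            control_model,
            SyntheticProtocol(kind="sinusoid", frequency=float(f), n_cycles=8))
            for f in freqs]
        spec = sweep_spectrum(traces)
        expected = spectrum_from_model(control_model, freqs)
        np.testing.assert_allclose(spec.elastic_modulus,
                                   expected.elastic_modulus, rtol=0.005)
        np.testing.assert_allclose(spec.viscous_modulus,
                                   expected.viscous_modulus, rtol=0.005)


class TestWorkAndPower:
    def test_zero_viscous_modulus_means_zero_work(self):
        spec = ComplexModulusSpectrum([10.0, 100.0, 500.0],
                                      [300.0, 400.0, 500.0],
                                      [0.0, 0.0, 0.0], amplitude=0.00125)
        w, p = work_and_power(spec)
        assert np.all(w == 0) and np.all(p == 0)

    def test_closed_form_value(self):
        spec = ComplexModulusSpectrum([150.0], [500.0], [-300.0],
                                      amplitude=0.00125)
        w, p = work_and_power(spec)
        assert w[0] == pytest.approx(np.pi * 1.25e-3**2 * 3.0e5, rel=1e-12)
        assert p[0] == pytest.approx(w[0] * 150.0, rel=1e-12)

    def test_amplitude_squared_scaling(self, control_model, sweep_frequencies):
        spec1 = spectrum_from_model(control_model, sweep_frequencies, 0.00125)
        spec2 = spectrum_from_model(control_model, sweep_frequencies, 0.0025)
        w1, _ = work_and_power(spec1)
        w2, _ = work_and_power(spec2)
        np.testing.assert_allclose(w2, 4.0 * w1, rtol=1e-12)

    def test_work_and_power_share_sign_and_ratio(self, control_model,
                                                 sweep_frequencies):
        spec = spectrum_from_model(control_model, sweep_frequencies)
        w, p = work_and_power(spec)
        assert np.all(np.sign(w) == np.sign(p))
        np.testing.assert_allclose(p, w * spec.frequencies, rtol=1e-12)


class TestSummary:
    def test_interior_peak_located(self, control_model, sweep_frequencies):
        spec = spectrum_from_model(control_model, sweep_frequencies)
        summary = summarize_spectrum(spec)
        assert sweep_frequencies[0] < summary.f_max < sweep_frequencies[-1]
        assert sweep_frequencies[0] < summary.f_wmax < sweep_frequencies[-1]
        assert not summary.boundary_flag
        # work peaks below power for this spectrum shape
        assert summary.f_wmax <= summary.f_max

    def test_monotone_power_flags_boundary(self):
        spec = ComplexModulusSpectrum([10.0, 100.0, 500.0],
                                      [300.0, 300.0, 300.0],
                                      [-100.0, -100.0, -100.0],
                                      amplitude=0.00125)
        with pytest.warns(UserWarning, match="boundary"):
            summary = summarize_spectrum(spec)
        assert summary.boundary_flag
        assert summary.f_max == 500.0

    def test_stiffness_needs_frequency_near_500(self):
        spec = ComplexModulusSpectrum([10.0, 50.0, 100.0],
                                      [300.0, 400.0, -100.0],
                                      [-10.0, -20.0, -5.0], amplitude=0.00125)
        with pytest.raises(ValueError, match="10%"):
            summarize_spectrum(spec)


class TestTension:
    @staticmethod
    def _flat_trace(level, n=2000, rate=1000.0):
        t = np.arange(n) / rate
        return LengthForceTrace(time=t, strain=np.zeros(n),
                                stress=np.full(n, float(level)),
                                drive_frequency=1.0, amplitude=0.0)

    def test_net_tension_is_active_minus_passive(self):
        m = measure_tension(self._flat_trace(1.94), self._flat_trace(3.07))
        assert m.net_F0 == pytest.approx(3.07 - 1.94)

    def test_equal_tensions_give_zero_net(self):
        m = measure_tension(self._flat_trace(2.0), self._flat_trace(2.0))
        assert m.net_F0 == 0.0

    def test_homozygote_style_subtraction(self):
        m = measure_tension(self._flat_trace(2.73), self._flat_trace(4.59))
        assert m.net_F0 == pytest.approx(1.86)

    def test_plateau_found_after_rise(self):
        t = np.arange(4000) / 1000.0
        stress = 3.0 * (1 - np.exp(-t / 0.2))
        tr = LengthForceTrace(time=t, strain=np.zeros_like(t), stress=stress,
                              drive_frequency=1.0, amplitude=0.0)
        m = measure_tension(self._flat_trace(1.0), tr)
        assert m.active_A0 == pytest.approx(3.0, rel=0.01)

    def test_no_plateau_raises(self):
        t = np.arange(1000) / 1000.0
        ramp = LengthForceTrace(time=t, strain=np.zeros_like(t),
                                stress=1.0 + 5.0 * t,
                                drive_frequency=1.0, amplitude=0.0)
        with pytest.raises(ValueError, match="plateau"):
            measure_tension(ramp, ramp)


class TestGeometry:
    def test_volume_and_stretch(self):
        g = FiberGeometry(length=1e-3, cross_sectional_area=2e-8)
        assert g.volume == pytest.approx(2e-11)
        assert g.stretched(2.0).length == pytest.approx(1.02e-3)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            FiberGeometry(length=0.0, cross_sectional_area=1e-8)
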