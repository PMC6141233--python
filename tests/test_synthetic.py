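"""Generators: ground-truth round trips, ensemble limits, reproducibility."""

import numpy as np
import pytest

from flymech.behavior import flight_index
from flymech.nyquist import NyquistFit, eval_model
from flymech.sinusoidal import extract_complex_modulus
from flymech.synthetic import (CrossBridgeParams, SyntheticProtocol,
                               gen_cardiac_trace, gen_dose_response,
                               gen_flight_counts, gen_linear_trace,
                               simulate_crossbridge_ensemble)


class TestProtocol:
    def test_undersampled_protocol_rejected(self):
        with pytest.raises(ValueError, match="20x"):
            SyntheticProtocol(kind="sinusoid", frequency=100.0, sample_rate=500.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            SyntheticProtocol(kind="ramp", frequency=1.0)

    def test_default_sampling_is_forty_per_cycle(self):
        proto = SyntheticProtocol(kind="sinusoid", frequency=100.0)
        assert proto.sample_rate == 4000.0


class TestLinearTrace:
    def test_pure_elastic_fiber_in_phase(self):
        model = NyquistFit(A=500.0, k=0.0, alpha=1.0, B=0.0, b=10.0,
                           C=0.0, c=100.0)
        proto = SyntheticProtocol(kind="sinusoid", frequency=123.0, n_cycles=6)
        tr = gen_linear_trace(model, proto)
        np.testing.assert_allclose(tr.stress, 500.0 * tr.strain, atol=1e-9)
        assert np.max(tr.stress) == pytest.approx(500.0 * proto.amplitude,
                                                  rel=1e-3)

    def test_b_process_high_frequency_plateau(self):
        """At f = 10 b the work-producing term has converged to within a
        few percent of its high-frequency limit -B (exactly -B/1.01 on the
        real axis), and the generated trace reproduces it."""
        b = 50.0
        model = NyquistFit(A=0.0, k=0.0, alpha=1.0, B=600.0, b=b, C=0.0, c=5000.0)
        f = 10.0 * b
        y = eval_model(model, f)
        assert y.real == pytest.approx(-600.0, rel=0.01)
        proto = SyntheticProtocol(kind="sinusoid", frequency=f, n_cycles=8)
        est = extract_complex_modulus(gen_linear_trace(model, proto))
        assert est.elastic == pytest.approx(y.real, rel=1e-6)
        assert est.viscous == pytest.approx(y.imag, rel=1e-6)

    def test_metadata_records_ground_truth(self, control_model):
        proto = SyntheticProtocol(kind="sinusoid", frequency=150.0)
        tr = gen_linear_trace(control_model, proto)
        y = eval_model(control_model, 150.0)
        assert tr.metadata["true_elastic"] == pytest.approx(y.real)
        assert tr.metadata["true_viscous"] == pytest.approx(y.imag)

    def test_wrong_protocol_kind_rejected(self, control_model):
        proto = SyntheticProtocol(kind="isometric", frequency=10.0)
        with pytest.raises(ValueError, match="sinusoid"):
            gen_linear_trace(control_model, proto)

    def test_seeded_noise_is_reproducible(self, control_model):
        proto = SyntheticProtocol(kind="sinusoid", frequency=150.0,
                                  noise_sd=0.02, seed=77)
        a = gen_linear_trace(control_model, proto)
        b = gen_linear_trace(control_model, proto)
        np.testing.assert_array_equal(a.stress, b.stress)


class TestEnsemble:
    def test_all_bound_limit_stress(self):
        """g -> 0 (duty -> 1): steady isometric stress equals
        n kappa d_stroke / area."""
        p = CrossBridgeParams(n_bridges=5000, f_att=200.0, g_det0=1e-6)
        proto = SyntheticProtocol(kind="isometric", frequency=10.0, n_cycles=5,
                                  sample_rate=200.0, seed=0)
        tr = simulate_crossbridge_ensemble(p, proto)
        expected = p.n_bridges * p.kappa * p.d_stroke / p.sarcomere_area * 1000.0
        assert np.mean(tr.stress) == pytest.approx(expected, rel=0.01)

    def test_balanced_rates_give_half_attachment(self):
        """f_att = g_det0: the two-state chain is attached half the time,
        within 3 Monte-Carlo standard errors over 10 seeds."""
        p = CrossBridgeParams(n_bridges=1000, f_att=500.0, g_det0=500.0)
        unit = p.n_bridges * p.kappa * p.d_stroke / p.sarcomere_area * 1000.0
        fracs = []
        for seed in range(10):
            proto = SyntheticProtocol(kind="isometric", frequency=4.0,
                                      n_cycles=2, sample_rate=100.0, seed=seed)
            tr = simulate_crossbridge_ensemble(p, proto)
            fracs.append(np.mean(tr.stress) / unit)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.5) < 3 * se + 1e-3

    def test_isometric_stress_monotone_in_duty_ratio(self):
        """Stress rises with attachment rate and falls with detachment
        rate over a 3x3 rate grid (5 seeds, MC error accounted)."""
        def mean_stress(f_att, g_det0):
            p = CrossBridgeParams(n_bridges=600, f_att=f_att, g_det0=g_det0)
            vals = []
            for seed in range(5):
                proto = SyntheticProtocol(kind="isometric", frequency=8.0,
                                          n_cycles=2, sample_rate=100.0,
                                          seed=seed)
                vals.append(np.mean(
                    simulate_crossbridge_ensemble(p, proto).stress))
            return np.mean(vals)

        f_grid = [100.0, 300.0, 900.0]
        g_grid = [800.0, 1600.0, 3200.0]
        table = {(f, g): mean_stress(f, g) for f in f_grid for g in g_grid}
        for g in g_grid:
            col = [table[(f, g)] for f in f_grid]
            assert col[0] < col[1] < col[2]
        for f in f_grid:
            row = [table[(f, g)] for g in g_grid]
            assert row[0] > row[1] > row[2]

    def test_atp_scaling_slows_detachment(self):
        """With atp_km set, low [ATP] slows detachment and raises the
        attached fraction (rigor-ward shift)."""
        p = CrossBridgeParams(n_bridges=1000, atp_km=5.0)
        proto = SyntheticProtocol(kind="isometric", frequency=8.0, n_cycles=2,
                                  sample_rate=100.0, seed=1)
        lo = simulate_crossbridge_ensemble(p, proto, atp_mM=0.5)
        hi = simulate_crossbridge_ensemble(p, proto, atp_mM=20.0)
        assert np.mean(lo.stress) > np.mean(hi.stress)

    def test_oversized_time_step_rejected(self):
        p = CrossBridgeParams(n_bridges=10, f_att=200.0, g_det0=2000.0)
        proto = SyntheticProtocol(kind="isometric", frequency=10.0,
                                  sample_rate=200.0)
        with pytest.raises(ValueError, match="overflow"):
            simulate_crossbridge_ensemble(p, proto, dt=1e-3)

    def test_fixed_seed_is_bit_reproducible(self):
        p = CrossBridgeParams(n_bridges=200)
        proto = SyntheticProtocol(kind="sinusoid", frequency=100.0, n_cycles=3,
                                  sample_rate=4000.0, seed=123)
        a = simulate_crossbridge_ensemble(p, proto)
        b = simulate_crossbridge_ensemble(p, proto)
        np.testing.assert_array_equal(a.stress, b.stress)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CrossBridgeParams(n_bridges=0)
        with pytest.raises(ValueError):
            CrossBridgeParams(f_att=-1.0)
        with pytest.raises(ValueError):
            CrossBridgeParams(g_strain_scale=0.0)

    def test_duty_ratio_definition(self):
        p = CrossBridgeParams(f_att=200.0, g_det0=2000.0)
        assert p.duty_ratio == pytest.approx(200.0 / 2200.0)


class TestDoseResponseGenerator:
    def test_half_saturation_point(self):
        df = gen_dose_response(vmax=2.0, km=0.4, basal=0.0, x_values=[0.4])
        assert df["rate"].iloc[0] == pytest.approx(1.0)

    def test_zero_concentration_gives_basal(self):
        df = gen_dose_response(vmax=2.0, km=0.4, basal=0.62, x_values=[0.0])
        assert df["rate"].iloc[0] == pytest.approx(0.62)

    def test_empty_concentrations_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gen_dose_response(vmax=1.0, km=1.0, basal=0.0, x_values=[])

    def test_truth_stored_and_noise_seeded(self):
        df = gen_dose_response(vmax=1.5, km=0.3, basal=0.1,
                               x_values=np.linspace(0.1, 2, 10),
                               noise_sd=0.05, seed=5)
        assert df.attrs["truth"]["km"] == 0.3
        df2 = gen_dose_response(vmax=1.5, km=0.3, basal=0.1,
                                x_values=np.linspace(0.1, 2, 10),
                                noise_sd=0.05, seed=5)
        np.testing.assert_array_equal(df["rate"], df2["rate"])


class TestFlightGenerator:
    def test_certain_upward_flight(self):
        counts = gen_flight_counts(1.0, 0.0, 0.0, 0.0, total=111, seed=0)
        assert counts.up == 111
        assert flight_index(counts) == 6.0

    def test_counts_sum_to_total(self):
        counts = gen_flight_counts(0.4, 0.3, 0.2, 0.1, total=111, seed=3)
        assert counts.total == 111

    def test_fixed_seed_repeats(self):
        a = gen_flight_counts(0.25, 0.25, 0.25, 0.25, total=50, seed=9)
        b = gen_flight_counts(0.25, 0.25, 0.25, 0.25, total=50, seed=9)
        assert (a.up, a.horizontal, a.down, a.none) == \
               (b.up, b.horizontal, b.down, b.none)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            gen_flight_counts(0.5, 0.5, 0.5, -0.5, total=10)
        with pytest.raises(ValueError, match="sum"):
            gen_flight_counts(0.5, 0.3, 0.1, 0.0, total=10)


class TestCardiacGenerator:
    def test_ground_truth_in_metadata(self):
        tr = gen_cardiac_trace(dd=60.0, sd=40.0, hp=0.5, si=0.2, n_beats=4)
        assert tr.metadata == {"dd": 60.0, "sd": 40.0, "hp": 0.5, "si": 0.2,
                               "n_beats": 4}

    def test_noise_is_seeded(self):
        kw = dict(dd=60.0, sd=40.0, hp=0.5, si=0.2, n_beats=4, noise_sd=0.5,
                  seed=21)
        a, b = gen_cardiac_trace(**kw), gen_cardiac_trace(**kw)
        np.testing.assert_array_equal(a.diameter, b.diameter)
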