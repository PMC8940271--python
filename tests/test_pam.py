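import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phototrace.core_io import Protocol, ProtocolPhase, Trace
from phototrace.errors import CoverageError, DomainError, QualityWarning
from phototrace.pam import (
    build_light_curve,
    compute_npq,
    compute_one_minus_ql,
    compute_phi_psii,
    compute_qt,
    decompose_npq_kinetics,
    extract_landmarks,
)
from phototrace.synthetic import (
    light_curve_protocol,
    simulate_pam_protocol,
    simulate_state_transition,
    wt_like,
)


class TestExtractLandmarks:
    def test_noiseless_simulation_matches_ground_truth(self, truth, protocol):
        trace, gt = simulate_pam_protocol(truth, protocol)
        lm = extract_landmarks(trace, protocol)
        assert lm.fm == pytest.approx(gt.landmarks.fm, abs=1e-9)
        assert lm.f0 == pytest.approx(gt.landmarks.f0, abs=1e-9)
        assert len(lm.steps) == len(gt.landmarks.steps)
        for got, want in zip(lm.steps, gt.landmarks.steps):
            assert got.fs == pytest.approx(want.fs, abs=1e-9)
            assert got.fm_prime == pytest.approx(want.fm_prime, abs=1e-9)
            assert got.f0_prime == pytest.approx(want.f0_prime, abs=1e-9)

    def test_flat_dark_pulse_reads_its_level(self):
        t = np.arange(0.0, 60.0, 0.1)
        v = np.where((t >= 50.0) & (t < 50.6), 2.0, 0.4)
        trace = Trace(time=t, values=v, channel="fluorescence")
        prot = Protocol((
            ProtocolPhase(0.0, 60.0, "dark", 0.0),
            ProtocolPhase(50.0, 50.6, "saturating_pulse", 6000.0),
        ))
        lm = extract_landmarks(trace, prot)
        assert lm.fm == pytest.approx(2.0)
        assert lm.f0 == pytest.approx(0.4)

    def test_missing_far_red_leaves_f0_prime_absent(self, truth):
        prot = light_curve_protocol(intensities=(150.0,), far_red_s=2.0)
        phases = tuple(p for p in prot.phases if p.kind != "far_red")
        trace, _ = simulate_pam_protocol(truth, Protocol(phases))
        lm = extract_landmarks(trace, Protocol(phases))
        assert lm.steps[0].f0_prime is None

    def test_fm_prime_above_fm_warns_but_returns(self, truth):
        prot = light_curve_protocol(intensities=(40.0,), step_s=60.0)
        trace, _ = simulate_pam_protocol(truth, prot)
        values = trace.values.copy()
        in_last_pulse = (trace.time >= prot.of_kind("saturating_pulse")[-1].start_s)
        values[in_last_pulse] *= 2.0  # corrupt the light pulse upward
        bad = Trace(time=trace.time, values=values, channel="fluorescence")
        with pytest.warns(QualityWarning, match="exceeds dark Fm"):
            lm = extract_landmarks(bad, prot)
        assert lm.findings


class TestQuenchingFormulas:
    @pytest.mark.parametrize("fm, fm_prime, expected", [
        (2.0, 1.0, 1.0),
        (1.5, 1.5, 0.0),
        (2.95, 1.0, 1.95),   # the end-of-light NPQ scale of a healthy plant
    ])
    def test_npq_arithmetic(self, fm, fm_prime, expected):
        assert compute_npq(fm, fm_prime) == pytest.approx(expected)

    def test_npq_rejects_nonpositive_fm_prime(self):
        with pytest.raises(DomainError):
            compute_npq(2.0, 0.0)

    @pytest.mark.parametrize("fm_prime, fs, expected", [
        (1.2, 1.2, 0.0),
        (1.2, 0.0, 1.0),
        (1.2, 0.6, 0.5),
    ])
    def test_phi_psii_arithmetic(self, fm_prime, fs, expected):
        assert compute_phi_psii(fm_prime, fs) == pytest.approx(expected)

    def test_phi_psii_negative_with_warning_when_fs_exceeds_fm_prime(self):
        with pytest.warns(QualityWarning):
            phi = compute_phi_psii(1.0, 1.2)
        assert phi == pytest.approx(-0.2)

    @pytest.mark.parametrize("fm_prime, fs, f0_prime, expected", [
        (1.0, 0.25, 0.25, 0.0),   # Fs at F0': all centers open
        (1.0, 1.0, 0.25, 1.0),    # Fs at Fm': all centers closed
        (1.0, 0.5, 0.25, 2.0 / 3.0),
    ])
    def test_one_minus_ql_arithmetic(self, fm_prime, fs, f0_prime, expected):
        assert compute_one_minus_ql(fm_prime, fs, f0_prime) == pytest.approx(
            expected
        )

    def test_one_minus_ql_degenerate_when_fm_prime_equals_f0_prime(self):
        with pytest.raises(DomainError):
            compute_one_minus_ql(0.5, 0.5, 0.5)

    @given(scale=st.floats(0.1, 10.0), npq=st.floats(0.0, 4.0))
    def test_npq_is_scale_invariant(self, scale, npq):
        fm_prime = 1.3
        fm = fm_prime * (1.0 + npq)
        assert compute_npq(fm * scale, fm_prime * scale) == pytest.approx(
            npq, rel=1e-9
        )


class TestLightCurve:
    def test_six_step_simulation_gives_six_monotone_npq_rows(self, truth,
                                                             protocol):
        _, gt = simulate_pam_protocol(truth, protocol)
        curve = build_light_curve(gt.landmarks)
        assert len(curve) == 6
        assert (np.diff(curve.npq) > 0).all()

    def test_zero_npq_truth_gives_zero_npq_rows(self, protocol):
        from dataclasses import replace

        truth = replace(wt_like(), npq_max=0.0, qz_amp=0.0)
        _, gt = simulate_pam_protocol(truth, protocol)
        curve = build_light_curve(gt.landmarks)
        np.testing.assert_allclose(curve.npq, 0.0, atol=1e-9)

    def test_single_step_gives_single_row(self, truth):
        prot = light_curve_protocol(intensities=(150.0,))
        _, gt = simulate_pam_protocol(truth, prot)
        assert len(build_light_curve(gt.landmarks)) == 1

    def test_derived_parameters_stay_in_unit_interval(self, truth, protocol):
        _, gt = simulate_pam_protocol(truth, protocol)
        curve = build_light_curve(gt.landmarks)
        assert curve.phi_psii.between(0, 1).all()
        assert curve.one_minus_ql.between(0, 1).all()


class TestStateTransitions:
    @pytest.mark.parametrize("st1, st2, expected", [
        (1.0, 1.0, 0.0),
        (1.0, 0.9, 0.1),
    ])
    def test_qt_arithmetic(self, st1, st2, expected):
        assert compute_qt(st1, st2) == pytest.approx(expected)

    def test_qt_rejects_nonpositive_reference(self):
        with pytest.raises(DomainError):
            compute_qt(0.0, 0.5)

    def test_simulated_amplitude_recovered(self):
        from dataclasses import replace

        truth = replace(wt_like(), qt_amp=0.05)
        st1, st2 = simulate_state_transition(truth)
        assert compute_qt(st1, st2) == pytest.approx(0.05, abs=1e-9)


class TestNpqKineticsDecomposition:
    @staticmethod
    def series(times, npqs):
        return pd.DataFrame({"time_s": times, "npq": npqs})

    def test_rise_then_relax_splits_into_qe_and_residual(self):
        t_light = np.arange(0.0, 601.0, 20.0)
        t_dark = np.arange(620.0, 1201.0, 20.0)
        npq = np.concatenate([
            1.95 * (1 - np.exp(-t_light / 120.0)) / (1 - np.exp(-5.0)),
            0.27 + (1.95 - 0.27) * np.exp(-(t_dark - 600.0) / 80.0),
        ])
        end, relaxed, qe, residual = decompose_npq_kinetics(
            self.series(np.concatenate([t_light, t_dark]), npq),
            light_off_time_s=600.0, relax_read_time_s=900.0,
        )
        assert end == pytest.approx(1.95)
        assert qe == pytest.approx(end - relaxed)
        assert residual == pytest.approx(relaxed)
        assert relaxed == pytest.approx(0.27, abs=0.05)

    def test_flat_zero_series_decomposes_to_zeros(self):
        t = np.arange(0.0, 1201.0, 20.0)
        out = decompose_npq_kinetics(self.series(t, np.zeros_like(t)),
                                     600.0, 900.0)
        assert out == (0.0, 0.0, 0.0, 0.0)

    def test_series_ending_before_light_off_is_coverage_error(self):
        t = np.arange(0.0, 400.0, 20.0)
        with pytest.raises(CoverageError):
            decompose_npq_kinetics(self.series(t, np.ones_like(t)),
                                   600.0, 900.0)

    def test_no_pulse_near_read_time_is_coverage_error(self):
        t = np.array([0.0, 300.0, 600.0, 620.0])
        with pytest.raises(CoverageError):
            decompose_npq_kinetics(self.series(t, np.ones_like(t)),
                                   600.0, 900.0)
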