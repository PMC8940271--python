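import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import optimize

from phototrace.core_io import Protocol, ProtocolPhase
from phototrace.errors import DomainError, ProtocolError
from phototrace.synthetic import (
    PORRA_MATRIX,
    SimulationGroundTruth,
    light_curve_protocol,
    mutant_like,
    simulate_dcmu_induction,
    simulate_ecs_experiment,
    simulate_flim_decay,
    simulate_grana_dataset,
    simulate_pam_protocol,
    simulate_pigment_extract,
    simulate_vj_series,
    wt_like,
)


def single_pulse_protocol():
    return Protocol((
        ProtocolPhase(0.0, 60.0, "dark", 0.0),
        ProtocolPhase(50.0, 50.6, "saturating_pulse", 6000.0),
    ))


class TestPamSimulator:
    def test_dark_pulse_reads_fm_dark(self, truth):
        trace, _ = simulate_pam_protocol(truth, single_pulse_protocol())
        assert trace.values.max() == pytest.approx(truth.fm_dark, abs=1e-12)

    def test_no_npq_means_fm_prime_equals_fm(self, protocol):
        truth = replace(wt_like(), npq_max=0.0, qz_amp=0.0)
        _, gt = simulate_pam_protocol(truth, protocol)
        for step in gt.landmarks.steps:
            assert step.fm_prime == pytest.approx(truth.fm_dark, rel=1e-9)

    def test_steady_state_npq_matches_hill_closed_form(self):
        # fast NPQ kinetics + long steps drive each step to steady state,
        # where (Fm - Fm')/Fm' must equal the generative Hill response
        truth = replace(wt_like(), tau_npq_ind_s=2.0, tau_npq_rel_s=2.0,
                        qz_amp=1e-12, tau_qz_s=1e9)
        protocol = light_curve_protocol(intensities=(850.0,), step_s=300.0)
        _, gt = simulate_pam_protocol(truth, protocol)
        step = gt.landmarks.steps[0]
        npq = (gt.landmarks.fm - step.fm_prime) / step.fm_prime
        assert npq == pytest.approx(truth.npq_ss(850.0), abs=1e-9)

    def test_requires_a_pulse(self, truth):
        bare = Protocol((ProtocolPhase(0.0, 10.0, "dark", 0.0),))
        with pytest.raises(ProtocolError):
            simulate_pam_protocol(truth, bare)

    def test_same_seed_is_bit_identical(self, truth, protocol):
        a, _ = simulate_pam_protocol(truth, protocol, noise_sd=0.02, seed=3)
        b, _ = simulate_pam_protocol(truth, protocol, noise_sd=0.02, seed=3)
        np.testing.assert_array_equal(a.values, b.values)


class TestEcsSimulator:
    def test_flash_amplitude_decays_to_140us_closed_form(self, truth):
        t520, t546, gt = simulate_ecs_experiment(truth, "flash_psi_only")
        pure = t520.values - t546.values
        read_t = gt["flash_time_s"] + 140e-6
        v = np.interp(read_t, t520.time, pure)
        expected = truth.ecs_amp_one_charge * np.exp(-140e-6 / truth.tau_atpase_s)
        assert v == pytest.approx(expected, rel=1e-6)

    def test_total_to_psi_only_ratio_is_one_plus_r(self, truth):
        _, _, g_tot = simulate_ecs_experiment(truth, "flash_total")
        _, _, g_psi = simulate_ecs_experiment(truth, "flash_psi_only")
        assert g_tot["amp_flash"] / g_psi["amp_flash"] == pytest.approx(
            1.0 + truth.r_psii_psi
        )

    def test_difference_recovers_pure_signal(self, truth):
        t520, t546, gt = simulate_ecs_experiment(truth, "light_off_decay")
        pure = t520.values - t546.values
        assert pure[0] == pytest.approx(gt["plateau"], abs=1e-12)

    def test_unknown_mode_rejected(self, truth):
        with pytest.raises(ProtocolError):
            simulate_ecs_experiment(truth, "sideways")

    def test_psii_inhibition_isolates_psi_rate(self, truth):
        _, _, gt = simulate_ecs_experiment(truth, "light_off_decay",
                                           psii_inhibited=True)
        assert gt["rate"] == pytest.approx(truth.rate_psi(gt["intensity"]))


class TestDcmuSimulator:
    def test_plateau_is_fm_dark(self, truth):
        tr = simulate_dcmu_induction(truth, intensity=80.0)
        assert tr.values[-1] == pytest.approx(truth.fm_dark, rel=1e-4)

    def test_complementary_area_is_reciprocal_rate(self, truth):
        tr = simulate_dcmu_induction(truth, intensity=80.0)
        v = (tr.values - truth.f0_dark) / (truth.fm_dark - truth.f0_dark)
        area = np.trapezoid(1.0 - v, tr.time)
        assert area == pytest.approx(1.0 / tr.meta["k_true"], rel=1e-3)

    def test_doubling_cross_section_halves_area(self, truth):
        wide = replace(truth, sigma_psii=2.0 * truth.sigma_psii)
        a = simulate_dcmu_induction(truth, 80.0).meta["k_true"]
        b = simulate_dcmu_induction(wide, 80.0).meta["k_true"]
        assert b == pytest.approx(2.0 * a)

    def test_nonpositive_intensity_rejected(self, truth):
        with pytest.raises(DomainError):
            simulate_dcmu_induction(truth, intensity=0.0)


class TestVjSimulator:
    def test_zero_interval_reads_v0(self, truth):
        df = simulate_vj_series(truth, [0.0, 1.0], "dark")
        assert df.vj.iloc[0] == pytest.approx(truth.vj_v0)

    def test_long_interval_reads_plateau(self, truth):
        df = simulate_vj_series(truth, [1000.0], "dark")
        assert df.vj.iloc[0] == pytest.approx(truth.vj_vinf_dark, abs=1e-9)

    def test_fit_on_exact_points_recovers_tau(self, truth):
        df = simulate_vj_series(truth, [0.05, 4, 8, 12, 16, 20, 24], "dark")

        def model(d, v0, vinf, tau):
            return vinf + (v0 - vinf) * np.exp(-d / tau)

        popt, _ = optimize.curve_fit(
            model, df.interval_s, df.vj, p0=(0.8, 0.3, 5.0)
        )
        assert popt[2] == pytest.approx(truth.tau_pq_ox_dark_s, abs=1e-6)

    def test_empty_intervals_rejected(self, truth):
        with pytest.raises(ProtocolError):
            simulate_vj_series(truth, [], "dark")


class TestFlimSimulator:
    def test_total_counts_equal_photon_budget(self):
        tr = simulate_flim_decay((0.6, 0.3, 0.1), (0.1, 0.9, 2.0),
                                 n_photons=123457, seed=1)
        assert tr.values.sum() == 123457

    def test_same_seed_reproduces_histogram(self):
        a = simulate_flim_decay((0.6, 0.3, 0.1), (0.1, 0.9, 2.0), seed=5)
        b = simulate_flim_decay((0.6, 0.3, 0.1), (0.1, 0.9, 2.0), seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_pure_exponential_loglinear_fit_recovers_tau(self):
        # independent oracle: weighted log-linear regression on the bins
        tr = simulate_flim_decay((1.0, 0.0, 0.0), (2.0, 0.9, 0.1),
                                 n_photons=10**6, n_bins=300, seed=2)
        c = tr.values
        ok = c > 30
        slope, _ = np.polyfit(tr.time[ok], np.log(c[ok]), 1, w=np.sqrt(c[ok]))
        assert -1.0 / slope == pytest.approx(2.0e-9, rel=0.01)

    def test_bad_amplitude_sum_rejected(self):
        with pytest.raises(DomainError):
            simulate_flim_decay((0.6, 0.3, 0.2), (0.1, 0.9, 2.0))


class TestGranaSimulator:
    def test_sample_mean_approaches_group_mean(self):
        df = simulate_grana_dataset(10**5, {"WT": 4.57}, {"WT": 500.0},
                                    80.0, seed=11)
        assert df.n_layers.mean() == pytest.approx(4.57, abs=0.02)

    def test_counts_have_support_at_least_one(self):
        df = simulate_grana_dataset(5000, {"g": 1.05}, {"g": 300.0}, 80.0,
                                    seed=3)
        assert (df.n_layers >= 1).all()
        assert (df.width_nm > 0).all()

    def test_mean_below_one_rejected(self):
        with pytest.raises(DomainError):
            simulate_grana_dataset(10, {"g": 0.5}, {"g": 300.0}, 80.0)

    def test_same_seed_reproducible(self):
        a = simulate_grana_dataset(100, {"g": 4.0}, {"g": 400.0}, 80.0, seed=9)
        b = simulate_grana_dataset(100, {"g": 4.0}, {"g": 400.0}, 80.0, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestPigmentSimulator:
    def test_forward_inverse_identity(self):
        from phototrace.pigments import PigmentSample, chl_from_absorbance

        a663, a646 = simulate_pigment_extract(10.0, 4.0)
        chl_a, chl_b = chl_from_absorbance(
            PigmentSample(a663_6=a663, a646_6=a646)
        )
        assert chl_a == pytest.approx(10.0, abs=1e-9)
        assert chl_b == pytest.approx(4.0, abs=1e-9)

    def test_pure_chl_a_solves_the_2x2_system(self):
        a663, a646 = simulate_pigment_extract(10.0, 0.0)
        conc = PORRA_MATRIX @ np.array([a663, a646])
        np.testing.assert_allclose(conc, [10.0, 0.0], atol=1e-9)

    def test_zero_maps_to_zero(self):
        assert simulate_pigment_extract(0.0, 0.0) == (0.0, 0.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            simulate_pigment_extract(-1.0, 0.0)


class TestGroundTruthObject:
    def test_flim_amps_must_sum_to_one(self):
        with pytest.raises(DomainError):
            SimulationGroundTruth(flim_amps=(0.5, 0.2, 0.2))

    def test_mutant_like_matches_stated_offsets(self):
        wt, mu = wt_like(), mutant_like()
        assert mu.sigma_psii == pytest.approx(0.75 * wt.sigma_psii)
        assert mu.r_psii_psi == pytest.approx(1.25 * wt.r_psii_psi)
        assert mu.npq_max == pytest.approx(0.70 * wt.npq_max)
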