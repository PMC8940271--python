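"""Synthetic instrument traces with known ground truth.

Every simulator here is a pure function of its parameters and a seed:
identical inputs give bit-identical outputs. The generative models are
deliberately simple closed forms so that downstream recovery can be tested
against exact expectations:

* PAM fluorescence uses a lake model of connected PSII antennae. The
  quenched maximal fluorescence is Fm'(t) = Fm / (1 + NPQ(t)), with NPQ
  relaxing first-order toward a hyperbolic (Hill) steady-state light
  response plus a slowly reversible zeaxanthin-like component. The closed
  PSII fraction under actinic light I is
  C(I) = sigma_II * I / (sigma_II * I + k_d + sigma_I * I / r), i.e.
  excitation pressure against PQ-pool reoxidation driven by PSI excitation
  plus a constant dark path k_d. The minimal fluorescence under light
  follows the Oxborough-Baker relation
  F0' = F0 / (F0/Fm + 1 - F0/Fm'), and the steady-state fluorescence
  follows the lake-model (connected-antenna) relation
  Fs = Fm' * F0' / (F0' + (1 - C) * (Fm' - F0')), under which the
  derived 1-qL parameter equals the closed fraction C exactly.
  Saturating pulses read Fm'; far-red windows read F0'.
* ECS: a single-turnover flash steps the 520-nm signal by one charge
  separation per photosystem (1 + r charges in total, 1 with PSII
  inhibited), decaying exponentially through ATP-synthase; light-off
  decays start from a steady plateau whose initial slope is
  -(rate * amp_one_charge). The 546-nm channel carries only a slow drift
  that is also added to the 520-nm channel, so the 520-546 difference is
  the pure electrochromic signal.
* TCSPC decays are multinomial photon draws from a (optionally
  Gaussian-IRF-convolved) sum of fixed-lifetime exponentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .antenna import exp_gauss_decay
from .core_io import Protocol, ProtocolPhase, Trace
from .errors import DomainError, ProtocolError
from .pam import FS_WINDOW_FRACTION, FluorescenceLandmarks, LandmarkStep

#: cross-section-to-rate unit constant (relative units; only ratios matter)
KAPPA = 1.0


@dataclass(frozen=True)
class SimulationGroundTruth:
    """Generative parameters of one genotype-like parameter set.

    Defaults describe a wild-type-like plant: PSII/PSI reaction-center
    ratio 1.37, substantial rapidly reversible NPQ, and a FLIM amplitude
    triple whose 100-ps component corresponds to a PSI chlorophyll share
    near 0.52 with the setup correction factor c = 0.49.
    """

    sigma_psii: float = 1.0      # relative PSII absorption cross-section
    sigma_psi: float = 1.0       # relative PSI absorption cross-section
    r_psii_psi: float = 1.37     # PSII/PSI reaction-center ratio
    fm_dark: float = 2.0         # dark-adapted maximal fluorescence (a.u.)
    f0_dark: float = 0.4         # dark-adapted minimal fluorescence (a.u.)
    npq_max: float = 2.4         # saturating steady-state NPQ
    npq_i50: float = 400.0       # half-saturation intensity (umol m-2 s-1)
    npq_hill: float = 1.3        # Hill exponent of the NPQ light response
    tau_npq_ind_s: float = 60.0  # NPQ induction time constant
    tau_npq_rel_s: float = 90.0  # NPQ relaxation time constant (dark)
    qz_amp: float = 0.30         # slowly reversible (zeaxanthin-like) NPQ
    tau_qz_s: float = 2000.0     # its induction/relaxation time constant
    qt_amp: float = 0.12         # state-transition amplitude (qT)
    k_reox_dark: float = 100.0   # PQ reoxidation, intensity-equivalent units
    ecs_amp_one_charge: float = 1e-3   # -dI/I per charge separation per PS
    tau_atpase_s: float = 0.2    # ECS decay time constant (ATP-synthase)
    cef_share: float = 0.2       # cyclic / total electron flow fraction
    tau_pq_ox_dark_s: float = 10.0     # PQ-pool reoxidation tau, dark
    tau_pq_ox_farred_s: float = 0.4    # PQ-pool reoxidation tau, far-red
    vj_v0: float = 0.85          # Vj immediately after a pulse
    vj_vinf_dark: float = 0.35   # Vj plateau after long dark interval
    vj_vinf_farred: float = 0.15 # Vj plateau after long far-red interval
    ecs_nuisance_amp: float = 5e-4     # slow 546-nm drift amplitude
    flim_amps: tuple[float, float, float] = (0.6885, 0.2000, 0.1115)
    flim_lifetimes_ns: tuple[float, float, float] = (0.1, 0.9, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "sigma_psii": self.sigma_psii, "sigma_psi": self.sigma_psi,
            "r_psii_psi": self.r_psii_psi, "fm_dark": self.fm_dark,
            "f0_dark": self.f0_dark, "tau_npq_ind_s": self.tau_npq_ind_s,
            "tau_npq_rel_s": self.tau_npq_rel_s, "tau_qz_s": self.tau_qz_s,
            "ecs_amp_one_charge": self.ecs_amp_one_charge,
            "tau_atpase_s": self.tau_atpase_s,
            "tau_pq_ox_dark_s": self.tau_pq_ox_dark_s,
            "tau_pq_ox_farred_s": self.tau_pq_ox_farred_s,
        }
        for name, v in positive.items():
            if not v > 0:
                raise DomainError(f"{name} must be > 0, got {v}")
        amps = np.asarray(self.flim_amps, dtype=float)
        if (amps < 0).any() or abs(amps.sum() - 1.0) > 1e-9:
            raise DomainError("flim_amps must be non-negative and sum to 1")

    def npq_ss(self, intensity: float) -> float:
        """Steady-state rapidly reversible NPQ at a given actinic intensity."""
        if intensity <= 0:
            return 0.0
        x = intensity ** self.npq_hill
        return self.npq_max * x / (self.npq_i50 ** self.npq_hill + x)

    def closed_fraction(self, intensity: float) -> float:
        """Steady-state fraction of closed PSII centers under intensity I."""
        if intensity <= 0:
            return 0.0
        exc = self.sigma_psii * intensity
        reox = self.k_reox_dark + self.sigma_psi * intensity / self.r_psii_psi
        return exc / (exc + reox)

    def rate_psii(self, intensity: float) -> float:
        """Photochemical rate of open PSII (e- s-1 PSII-1, relative units)."""
        return KAPPA * self.sigma_psii * intensity

    def rate_psi(self, intensity: float) -> float:
        return KAPPA * self.sigma_psi * intensity

    def rate_total_per_ps(self, intensity: float) -> float:
        """Reaction-center-weighted mean photochemical rate per photosystem."""
        r = self.r_psii_psi
        return (r * self.rate_psii(intensity) + self.rate_psi(intensity)) / (1 + r)


def wt_like() -> SimulationGroundTruth:
    """Wild-type-like parameter set (the defaults)."""
    return SimulationGroundTruth()


def mutant_like() -> SimulationGroundTruth:
    """Antenna-mutant-like set: PSII cross-section -25%, reaction-center
    ratio +25%, maximal NPQ -30%, reduced state transitions, larger fast
    FLIM amplitude (PSI chlorophyll share near 0.60), and faster, more
    complete far-red PQ-pool oxidation (the reduced PSII excitation under
    far-red leaves less pool re-reduction opposing the PSI drain, so the
    pool drains quicker and to a more oxidized plateau). Dark reoxidation
    is unchanged."""
    base = wt_like()
    return replace(
        base,
        sigma_psii=base.sigma_psii * 0.75,
        r_psii_psi=base.r_psii_psi * 1.25,
        npq_max=base.npq_max * 0.70,
        qt_amp=0.02,
        tau_pq_ox_farred_s=base.tau_pq_ox_farred_s * 0.75,
        vj_vinf_farred=0.10,
        flim_amps=(0.7538, 0.1600, 0.0862),
    )


# ---------------------------------------------------------------------------
# protocol builders

def light_curve_protocol(
    intensities=(40.0, 95.0, 150.0, 380.0, 620.0, 850.0),
    step_s: float = 300.0,
    dark_s: float = 60.0,
    pulse_s: float = 0.6,
    far_red_s: float = 2.0,
) -> Protocol:
    """Stepped-actinic PAM light-curve protocol: dark Fm pulse, then one
    actinic step per intensity, each closed by a saturating pulse and a
    far-red F0' window."""
    phases = [
        ProtocolPhase(0.0, dark_s, "dark", 0.0),
        ProtocolPhase(dark_s - 10.0, dark_s - 10.0 + pulse_s,
                      "saturating_pulse", 6000.0),
    ]
    t = dark_s
    for i in intensities:
        phases.append(ProtocolPhase(t, t + step_s, "actinic", float(i)))
        phases.append(ProtocolPhase(t + step_s, t + step_s + pulse_s,
                                    "saturating_pulse", 6000.0))
        phases.append(ProtocolPhase(t + step_s + pulse_s,
                                    t + step_s + pulse_s + far_red_s,
                                    "far_red", 30.0))
        t += step_s + pulse_s + far_red_s
    phases.sort(key=lambda p: p.start_s)
    return Protocol(tuple(phases))


def npq_kinetics_protocol(
    actinic: float = 1000.0,
    light_s: float = 600.0,
    dark_relax_s: float = 600.0,
    pulse_every_s: float = 20.0,
    pulse_s: float = 0.6,
    dark_s: float = 60.0,
) -> Protocol:
    """NPQ induction/relaxation protocol: dark Fm pulse, a long actinic
    phase and a dark relaxation phase, both probed by pulses every 20 s."""
    phases = [
        ProtocolPhase(0.0, dark_s, "dark", 0.0),
        ProtocolPhase(dark_s - 10.0, dark_s - 10.0 + pulse_s,
                      "saturating_pulse", 6000.0),
        ProtocolPhase(dark_s, dark_s + light_s, "actinic", actinic),
        ProtocolPhase(dark_s + light_s, dark_s + light_s + dark_relax_s,
                      "dark", 0.0),
    ]
    t = dark_s + pulse_every_s
    while t + pulse_s <= dark_s + light_s + dark_relax_s:
        phases.append(ProtocolPhase(t, t + pulse_s, "saturating_pulse", 6000.0))
        t += pulse_every_s
    phases.sort(key=lambda p: p.start_s)
    return Protocol(tuple(phases))


# ---------------------------------------------------------------------------
# PAM simulator

@dataclass(frozen=True)
class PamGroundTruth:
    """Exact noiseless landmarks and derived curves emitted by the simulator."""

    landmarks: FluorescenceLandmarks
    light_curve: pd.DataFrame
    npq_series: pd.DataFrame   # (time_s, npq) at every pulse


def _segment_contexts(protocol: Protocol, t0: float, t1: float):
    """Split [t0, t1) at phase boundaries; each segment gets the governing
    phase (latest phase containing its midpoint), or dark if uncovered."""
    cuts = {t0, t1}
    for p in protocol.phases:
        for t in (p.start_s, p.end_s):
            if t0 < t < t1:
                cuts.add(t)
    edges = sorted(cuts)
    out = []
    for a, b in zip(edges, edges[1:]):
        phase = protocol.phase_at((a + b) / 2)
        kind = phase.kind if phase else "dark"
        inten = phase.intensity if phase else 0.0
        out.append((a, b, kind, inten))
    return out


def simulate_pam_protocol(
    truth: SimulationGroundTruth,
    protocol: Protocol,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_hz: float = 10.0,
) -> tuple[Trace, PamGroundTruth]:
    """Render a PAM fluorescence trace for a light protocol.

    Returns the (optionally noisy) trace and the exact noiseless ground
    truth: landmarks read with the same window conventions the extractor
    uses, the derived light curve, and NPQ at every pulse.
    """
    pulses = protocol.of_kind("saturating_pulse")
    if not pulses:
        raise ProtocolError("PAM simulation needs at least one saturating pulse")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    starts = [p.start_s for p in protocol.phases]
    ends = [p.end_s for p in protocol.phases]
    t0, t1 = min(starts), max(ends)
    dt = 1.0 / sample_hz
    time = t0 + np.arange(int(round((t1 - t0) / dt))) * dt

    fm, f0 = truth.fm_dark, truth.f0_dark
    npq = np.empty_like(time)
    closed = np.empty_like(time)
    is_pulse = np.zeros(time.shape, dtype=bool)
    is_farred = np.zeros(time.shape, dtype=bool)

    qe, qz = 0.0, 0.0          # fast and slow NPQ component state
    prev_ctx = (0.0, truth.tau_npq_rel_s, 0.0, 0.0)  # qe tgt, tau, qz tgt, C
    for a, b, kind, inten in _segment_contexts(protocol, t0, t1):
        if kind == "actinic":
            qe_tgt = truth.npq_ss(inten)
            tau = truth.tau_npq_ind_s if qe_tgt >= qe else truth.tau_npq_rel_s
            qz_tgt = truth.qz_amp * (qe_tgt / truth.npq_max if truth.npq_max else 0)
            c_val = truth.closed_fraction(inten)
            prev_ctx = (qe_tgt, tau, qz_tgt, c_val)
        elif kind in ("dark", "far_red", "laser_flash"):
            qe_tgt, tau, qz_tgt, c_val = 0.0, truth.tau_npq_rel_s, 0.0, 0.0
            prev_ctx = (qe_tgt, tau, qz_tgt, c_val)
        else:  # saturating pulse: NPQ keeps evolving in the ambient context
            qe_tgt, tau, qz_tgt, c_val = prev_ctx
        mask = (time >= a) & (time < b)
        rel = time[mask] - a
        npq[mask] = (
            qe_tgt + (qe - qe_tgt) * np.exp(-rel / tau)
            + qz_tgt + (qz - qz_tgt) * np.exp(-rel / truth.tau_qz_s)
        )
        closed[mask] = c_val
        if kind == "saturating_pulse":
            is_pulse[mask] = True
        elif kind == "far_red":
            is_farred[mask] = True
        span = b - a
        qe = qe_tgt + (qe - qe_tgt) * np.exp(-span / tau)
        qz = qz_tgt + (qz - qz_tgt) * np.exp(-span / truth.tau_qz_s)

    fm_prime = fm / (1.0 + npq)
    f0_prime = f0 / (f0 / fm + 1.0 - f0 / fm_prime)
    # lake-model steady-state fluorescence: 1-qL recovers C exactly
    signal = fm_prime * f0_prime / (
        f0_prime + (1.0 - closed) * (fm_prime - f0_prime)
    )
    signal[is_pulse] = fm_prime[is_pulse]
    signal[is_farred] = f0_prime[is_farred]

    truth_landmarks, lc, series = _pam_ground_truth(
        protocol, time, signal, fm_prime, fm, f0
    )
    values = signal
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    trace = Trace(time=time, values=values, channel="fluorescence",
                  meta={"simulated": True, "noise_sd": noise_sd, "seed": seed})
    return trace, PamGroundTruth(truth_landmarks, lc, series)


def _pam_ground_truth(protocol, time, signal, fm_prime_t, fm, f0):
    from .pam import (build_light_curve, compute_npq)

    pulses = protocol.of_kind("saturating_pulse")
    actinics = protocol.of_kind("actinic")
    far_reds = protocol.of_kind("far_red")

    def window(a, b):
        return signal[(time >= a) & (time < b)]

    steps = []
    series_rows = []
    fm_gt = float(np.mean(window(pulses[0].start_s, pulses[0].end_s)))
    for pulse in pulses[1:]:
        fm_p = float(np.mean(window(pulse.start_s, pulse.end_s)))
        series_rows.append({"time_s": pulse.start_s,
                            "npq": compute_npq(fm_gt, fm_p)})
        prior = [a for a in actinics if a.end_s <= pulse.start_s + 1e-12]
        if not prior:
            continue
        step = prior[-1]
        w = (step.end_s - step.start_s) * FS_WINDOW_FRACTION
        fs = float(np.mean(window(step.end_s - w, step.end_s)))
        f0p = None
        following = [f for f in far_reds if f.start_s >= pulse.end_s - 1e-12]
        if following:
            vals = window(following[0].start_s, following[0].end_s)
            if len(vals):
                f0p = float(np.min(vals))
        steps.append(LandmarkStep(step.intensity, fs, fm_p, f0p))
    dark_pre = signal[(time >= time[0]) & (time < pulses[0].start_s)]
    landmarks = FluorescenceLandmarks(
        fm=fm_gt, f0=float(np.median(dark_pre)), steps=tuple(steps)
    )
    return landmarks, build_light_curve(landmarks), pd.DataFrame(series_rows)


def simulate_state_transition(
    truth: SimulationGroundTruth, noise_sd: float = 0.0, seed: int = 0
) -> tuple[float, float]:
    """Maximal fluorescence at the end of State 1 and State 2 light phases.

    State 2 redistributes mobile LHCII toward PSI, quenching Fm by the
    state-transition amplitude: Fm_St2 = Fm_St1 * (1 - qt_amp).
    """
    rng = np.random.default_rng(seed)
    fm_st1 = truth.fm_dark * 0.95
    fm_st2 = fm_st1 * (1.0 - truth.qt_amp)
    if noise_sd > 0:
        fm_st1 += rng.normal(0.0, noise_sd)
        fm_st2 += rng.normal(0.0, noise_sd)
    return fm_st1, fm_st2


# ---------------------------------------------------------------------------
# ECS simulator

ECS_MODES = ("flash_total", "flash_psi_only", "light_off_decay",
             "farred_off_decay")


def simulate_ecs_experiment(
    truth: SimulationGroundTruth,
    mode: str,
    noise_sd: float = 0.0,
    seed: int = 0,
    intensity: float = 80.0,
    psii_inhibited: bool = False,
) -> tuple[Trace, Trace, dict]:
    """Simulate a dual-wavelength (520/546 nm) ECS measurement.

    Flash modes step the signal by one charge separation per photosystem
    (``flash_total``: 1 + r charges; ``flash_psi_only``: 1 charge, PSII
    inhibited) decaying with the ATP-synthase time constant. Off-decay
    modes start from a steady plateau whose post-off initial slope is
    -(rate * amp_one_charge), with rate the total electron flow
    (``light_off_decay``; the PSI-only rate when ``psii_inhibited``,
    emulating DCMU + hydroxylamine infiltration) or the cyclic flow under
    far-red (``farred_off_decay``). Noise is multiplicative: each sample
    of each channel is scaled by (1 + N(0, noise_sd)), emulating shot and
    detection noise proportional to the transmitted intensity.

    Returns (trace_520, trace_546, ground_truth_dict).
    """
    if mode not in ECS_MODES:
        raise ProtocolError(f"unknown ECS mode {mode!r}; expected {ECS_MODES}")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    amp1 = truth.ecs_amp_one_charge
    tau = truth.tau_atpase_s
    gt: dict = {"mode": mode, "amp_one_charge": amp1, "tau_atpase_s": tau}

    if mode.startswith("flash"):
        flash_time = 0.005
        dt = 1e-5
        time = np.arange(0.0, 0.02, dt)
        n_charges = (1.0 + truth.r_psii_psi) if mode == "flash_total" else 1.0
        amp = amp1 * n_charges
        pure = np.where(time >= flash_time,
                        amp * np.exp(-(np.maximum(time - flash_time, 0.0)) / tau),
                        0.0)
        gt.update(flash_time_s=flash_time, amp_flash=amp,
                  amp_at_140us=amp * np.exp(-140e-6 / tau),
                  r_psii_psi=truth.r_psii_psi)
    else:
        off_time = 0.05
        dt = 2e-6   # us-class sampling keeps the slope estimator tight
        time = np.arange(0.0, 0.1, dt)
        if mode == "light_off_decay":
            rate = (truth.rate_psi(intensity) if psii_inhibited
                    else truth.rate_total_per_ps(intensity))
        else:
            rate = truth.cef_share * truth.rate_total_per_ps(intensity)
        plateau = rate * amp1 * tau   # so the initial decay slope is -rate*amp1
        pure = np.where(time < off_time, plateau,
                        plateau * np.exp(-(np.maximum(time - off_time, 0.0)) / tau))
        gt.update(off_time_s=off_time, rate=rate, plateau=plateau,
                  intensity=intensity, psii_inhibited=psii_inhibited)

    nuisance = truth.ecs_nuisance_amp * (time - time[0]) / (time[-1] - time[0])
    v520 = pure + nuisance
    v546 = nuisance.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v520 = v520 * (1.0 + rng.normal(0.0, noise_sd, size=time.shape))
        v546 = v546 * (1.0 + rng.normal(0.0, noise_sd, size=time.shape))
    meta = {"simulated": True, "mode": mode, "seed": seed}
    return (
        Trace(time=time, values=v520, channel="ecs_520", meta=dict(meta)),
        Trace(time=time, values=v546, channel="ecs_546", meta=dict(meta)),
        gt,
    )


# ---------------------------------------------------------------------------
# DCMU induction, Vj, FLIM, grana, pigments

def simulate_dcmu_induction(
    truth: SimulationGroundTruth,
    intensity: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int = 3000,
) -> Trace:
    """Fluorescence induction of a DCMU-blocked leaf at low light.

    With PSII reduction blocked after one charge separation, fluorescence
    rises as F(t) = F0 + (Fm - F0) * (1 - exp(-k t)) with
    k = sigma_psii * intensity (relative units); the complementary area
    above the normalized curve is 1/k.
    """
    if intensity <= 0:
        raise DomainError(f"intensity must be > 0, got {intensity}")
    k = KAPPA * truth.sigma_psii * intensity
    t_end = 12.0 / k
    time = np.linspace(0.0, t_end, n_samples)
    values = truth.f0_dark + (truth.fm_dark - truth.f0_dark) * (
        1.0 - np.exp(-k * time)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return Trace(time=time, values=values, channel="fluorescence",
                 meta={"simulated": True, "dcmu": True, "k_true": k,
                       "intensity": intensity, "seed": seed})


def simulate_vj_series(
    truth: SimulationGroundTruth,
    intervals: list[float],
    mode: str = "dark",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Vj as a function of the dark or far-red interval between pulses.

    Vj decays from its post-pulse value toward the reoxidized plateau with
    the PQ-pool reoxidation time constant of the chosen mode:
    Vj(D) = V_inf + (V0 - V_inf) * exp(-D / tau).
    """
    if len(intervals) == 0:
        raise ProtocolError("interval list is empty")
    if mode not in ("dark", "far_red"):
        raise ProtocolError(f"mode must be 'dark' or 'far_red', got {mode!r}")
    d = np.asarray(intervals, dtype=float)
    if mode == "dark":
        tau, v_inf = truth.tau_pq_ox_dark_s, truth.vj_vinf_dark
    else:
        tau, v_inf = truth.tau_pq_ox_farred_s, truth.vj_vinf_farred
    vj = v_inf + (truth.vj_v0 - v_inf) * np.exp(-d / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vj = vj + rng.normal(0.0, noise_sd, size=vj.shape)
    return pd.DataFrame({"interval_s": d, "vj": vj})


def simulate_flim_decay(
    amps,
    lifetimes_ns,
    irf_sigma_ps: float = 0.0,
    n_photons: int = 10**6,
    bin_ps: float = 32.0,
    n_bins: int = 780,
    seed: int = 0,
) -> Trace:
    """Multinomial TCSPC histogram of a multi-exponential decay.

    Expected counts per bin follow sum_i a_i * exp(-t/tau_i), optionally
    convolved with a Gaussian instrument response of width
    ``irf_sigma_ps``; ``n_photons`` photons are drawn multinomially, so
    the histogram total is exact.
    """
    amps = np.asarray(amps, dtype=float)
    taus = np.asarray(lifetimes_ns, dtype=float) * 1e-9
    if abs(amps.sum() - 1.0) > 1e-9:
        raise DomainError(f"amplitudes must sum to 1, got {amps.sum()!r}")
    if (amps < 0).any():
        raise DomainError("amplitudes must be non-negative")
    t0 = 10.0 * irf_sigma_ps * 1e-12
    time = (np.arange(n_bins) + 0.5) * bin_ps * 1e-12
    sigma = irf_sigma_ps * 1e-12
    model = np.zeros_like(time)
    for a, tau in zip(amps, taus):
        model += a * exp_gauss_decay(time, tau, sigma, t0)
    p = model / model.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_photons, p)
    return Trace(time=time, values=counts.astype(float), channel="tcspc",
                 meta={"simulated": True, "bin_ps": bin_ps, "t0_s": t0,
                       "irf_sigma_ps": irf_sigma_ps, "seed": seed})


def simulate_grana_dataset(
    n_per_group: int,
    mean_stacks_by_group: dict,
    width_mean_by_group: dict,
    width_sd: float,
    seed: int = 0,
    covariate_mean: float = 5.0,
    covariate_slope: float = 0.0,
) -> pd.DataFrame:
    """Morphometry table of grana stack counts and widths per genotype.

    Stack counts are 1 + Poisson(mean - 1) (a granum has at least one
    layer); widths are Normal truncated at 0. An optional log-linear
    covariate effect (grana per section) can modulate the count mean.
    """
    for g, m in mean_stacks_by_group.items():
        if m < 1:
            raise DomainError(f"mean stacks for {g!r} must be >= 1, got {m}")
    rng = np.random.default_rng(seed)
    frames = []
    for g in sorted(mean_stacks_by_group):
        lam = mean_stacks_by_group[g] - 1.0
        cov = rng.poisson(covariate_mean - 1, size=n_per_group) + 1
        lam_i = lam * np.exp(covariate_slope * (cov - covariate_mean))
        counts = 1 + rng.poisson(lam_i)
        wm = width_mean_by_group[g]
        a = (0.0 - wm) / width_sd
        widths = stats.truncnorm.rvs(a, np.inf, loc=wm, scale=width_sd,
                                     size=n_per_group, random_state=rng)
        frames.append(pd.DataFrame({
            "genotype": g, "n_layers": counts, "width_nm": widths,
            "grana_per_section": cov,
        }))
    return pd.concat(frames, ignore_index=True)


#: Porra-style coefficient matrix for buffered 80% acetone:
#: [chl_a, chl_b] = PORRA_MATRIX @ [A663.6, A646.6]  (ug/ml)
PORRA_MATRIX = np.array([[12.25, -2.55],
                         [-4.91, 20.31]])


def simulate_pigment_extract(chl_a: float, chl_b: float) -> tuple[float, float]:
    """Absorbances (A663.6, A646.6) of an extract with known chlorophyll
    content, by inverting the linear quantification system."""
    if chl_a < 0 or chl_b < 0:
        raise DomainError("concentrations must be non-negative")
    a663, a646 = np.linalg.solve(PORRA_MATRIX, [chl_a, chl_b])
    return float(a663), float(a646)
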