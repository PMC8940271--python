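"""Pulse-amplitude-modulated (PAM) fluorescence quenching analysis.

Extracts the classical fluorescence landmarks from an annotated PAM trace
and derives the quenching parameters of a light curve:

* NPQ = (Fm - Fm') / Fm'          (non-photochemical quenching)
* PhiPSII = (Fm' - Fs) / Fm'      (PSII operating quantum yield)
* 1 - qL = 1 - [(Fm'-Fs)/(Fm'-F0')] * (F0'/Fs)
                                   (closed PSII fraction, lake model)
* qT = (Fm_St1 - Fm_St2) / Fm_St1  (state-transition quenching)

Landmark conventions: Fm is the mean over the first saturating pulse given
in darkness; F0 the median of the pre-pulse dark window; per light step,
Fm' is the mean over the step's pulse window (the window is the pulse
plateau, and the plateau mean — unlike the window maximum — is an unbiased
estimator under detector noise), Fs the mean of the last 5% of samples of
the actinic phase preceding the pulse, and F0' the minimum inside the
far-red window that follows the step (far-red light oxidizes the electron
transport chain, re-opening PSII). No smoothing is applied before
extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Protocol, ProtocolPhase, Trace
from .errors import (
    CoverageError,
    DomainError,
    ProtocolError,
    QualityWarning,
    ResolutionError,
)

#: fraction of the actinic phase used as the steady-state (Fs) window
FS_WINDOW_FRACTION = 0.05


@dataclass(frozen=True)
class LandmarkStep:
    """Landmarks of one actinic light step."""

    intensity: float
    fs: float
    fm_prime: float
    f0_prime: float | None = None


@dataclass(frozen=True)
class FluorescenceLandmarks:
    """Fm, F0 and the per-step landmarks of a PAM light curve."""

    fm: float
    f0: float
    steps: tuple[LandmarkStep, ...] = ()
    findings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        object.__setattr__(self, "findings", tuple(self.findings))


def _samples_in(trace: Trace, start: float, end: float) -> np.ndarray:
    mask = (trace.time >= start) & (trace.time < end)
    return trace.values[mask]


def extract_landmarks(trace: Trace, protocol: Protocol) -> FluorescenceLandmarks:
    """Extract Fm, F0 and per-step (intensity, Fs, Fm', F0') from a PAM trace.

    The first saturating pulse must occur in darkness and provides Fm; each
    later pulse closes the actinic phase immediately preceding it. Pulse
    levels are plateau means (see module docstring). A missing
    far-red window leaves that step's F0' absent (``None``) without error.
    """
    pulses = protocol.of_kind("saturating_pulse")
    if not pulses:
        raise ProtocolError("protocol contains no saturating pulse")
    findings: list[str] = []

    def pulse_level(p: ProtocolPhase) -> float:
        vals = _samples_in(trace, p.start_s, p.end_s)
        if len(vals) < 3:
            raise ResolutionError(
                f"pulse [{p.start_s}, {p.end_s}) holds {len(vals)} samples (<3)"
            )
        return float(np.mean(vals))

    first = pulses[0]
    fm = pulse_level(first)
    dark_pre = _samples_in(trace, trace.span[0], first.start_s)
    if len(dark_pre) == 0:
        raise CoverageError("no dark samples before the first saturating pulse")
    f0 = float(np.median(dark_pre))

    actinics = protocol.of_kind("actinic")
    far_reds = protocol.of_kind("far_red")
    steps: list[LandmarkStep] = []
    for pulse in pulses[1:]:
        prior = [a for a in actinics if a.end_s <= pulse.start_s + 1e-12]
        if not prior:
            findings.append(
                f"pulse at {pulse.start_s} s has no preceding actinic phase; skipped"
            )
            continue
        step_phase = prior[-1]
        fm_prime = pulse_level(pulse)
        if fm_prime > fm * (1 + 1e-6):
            findings.append(
                f"Fm' {fm_prime:.6g} at {pulse.start_s} s exceeds dark Fm {fm:.6g}"
            )
        window = (step_phase.end_s - step_phase.start_s) * FS_WINDOW_FRACTION
        fs_vals = _samples_in(trace, step_phase.end_s - window, step_phase.end_s)
        if len(fs_vals) == 0:
            raise ResolutionError(
                f"no samples in Fs window before pulse at {pulse.start_s} s"
            )
        fs = float(np.mean(fs_vals))
        f0_prime: float | None = None
        following = [f for f in far_reds if f.start_s >= pulse.end_s - 1e-12]
        if following:
            fr = following[0]
            fr_vals = _samples_in(trace, fr.start_s, fr.end_s)
            if len(fr_vals):
                f0_prime = float(np.min(fr_vals))
        steps.append(LandmarkStep(step_phase.intensity, fs, fm_prime, f0_prime))
    if findings:
        warnings.warn("; ".join(findings), QualityWarning, stacklevel=2)
    return FluorescenceLandmarks(fm=fm, f0=f0, steps=tuple(steps),
                                 findings=tuple(findings))


def compute_npq(fm: float, fm_prime: float) -> float:
    """Non-photochemical quenching, (Fm - Fm') / Fm'."""
    if fm_prime <= 0:
        raise DomainError(f"fm_prime must be > 0, got {fm_prime}")
    return (fm - fm_prime) / fm_prime


def compute_phi_psii(fm_prime: float, fs: float) -> float:
    """PSII operating quantum yield, (Fm' - Fs) / Fm'.

    If Fs exceeds Fm' the (negative) value is returned with a
    :class:`QualityWarning` rather than clamped.
    """
    if fm_prime <= 0:
        raise DomainError(f"fm_prime must be > 0, got {fm_prime}")
    phi = (fm_prime - fs) / fm_prime
    if fs > fm_prime:
        warnings.warn(
            f"Fs {fs:.6g} exceeds Fm' {fm_prime:.6g}: PhiPSII negative",
            QualityWarning, stacklevel=2,
        )
    return phi


def compute_one_minus_ql(fm_prime: float, fs: float, f0_prime: float) -> float:
    """Fraction of closed PSII centers, 1 - [(Fm'-Fs)/(Fm'-F0')] * (F0'/Fs)."""
    if fm_prime == f0_prime:
        raise DomainError("Fm' == F0': closed fraction undefined")
    if fs <= 0 or f0_prime <= 0:
        raise DomainError("Fs and F0' must be > 0")
    return 1.0 - ((fm_prime - fs) / (fm_prime - f0_prime)) * (f0_prime / fs)


def build_light_curve(landmarks: FluorescenceLandmarks) -> pd.DataFrame:
    """Per-step NPQ / PhiPSII / 1-qL table, ordered by intensity.

    Steps whose landmarks break a formula's domain get NaN for that column
    and a note in the ``finding`` column instead of an exception.
    """
    rows = []
    for step in sorted(landmarks.steps, key=lambda s: s.intensity):
        row: dict = {"intensity": step.intensity, "finding": ""}
        notes = []
        try:
            row["npq"] = compute_npq(landmarks.fm, step.fm_prime)
        except DomainError as e:
            row["npq"] = np.nan
            notes.append(str(e))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", QualityWarning)
            try:
                row["phi_psii"] = compute_phi_psii(step.fm_prime, step.fs)
            except DomainError as e:
                row["phi_psii"] = np.nan
                notes.append(str(e))
        if step.f0_prime is None:
            row["one_minus_ql"] = np.nan
            notes.append("no far-red window: F0' absent")
        else:
            try:
                row["one_minus_ql"] = compute_one_minus_ql(
                    step.fm_prime, step.fs, step.f0_prime
                )
            except DomainError as e:
                row["one_minus_ql"] = np.nan
                notes.append(str(e))
        row["finding"] = "; ".join(notes)
        rows.append(row)
    return pd.DataFrame(rows, columns=["intensity", "npq", "phi_psii",
                                       "one_minus_ql", "finding"])


def compute_qt(fm_st1: float, fm_st2: float) -> float:
    """State-transition quenching, (Fm_St1 - Fm_St2) / Fm_St1.

    Fm_St1 and Fm_St2 are the maximal fluorescence at the end of the
    State 1 (red + far-red) and State 2 (red only) light phases.
    """
    if fm_st1 <= 0:
        raise DomainError(f"fm_st1 must be > 0, got {fm_st1}")
    return (fm_st1 - fm_st2) / fm_st1


def decompose_npq_kinetics(
    npq_series: pd.DataFrame,
    light_off_time_s: float,
    relax_read_time_s: float,
    tolerance_s: float = 30.0,
) -> tuple[float, float, float, float]:
    """Two-point decomposition of an NPQ induction/relaxation series.

    ``npq_series`` holds one row per saturating pulse with columns
    ``time_s`` and ``npq``. Returns ``(npq_end_light, npq_relaxed, qe,
    residual)`` where qE — the rapidly reversible, energy-dependent
    component — is NPQ at the end of the light phase minus NPQ at the pulse
    nearest ``relax_read_time_s`` after light-off; the remainder is the
    slowly reversible residual.
    """
    t = npq_series["time_s"].to_numpy(dtype=float)
    npq = npq_series["npq"].to_numpy(dtype=float)
    if t.size == 0 or t[-1] < light_off_time_s:
        raise CoverageError("series ends before the light-off time")
    in_light = t <= light_off_time_s
    if not in_light.any():
        raise CoverageError("no pulses at or before light-off")
    npq_end_light = float(npq[in_light][-1])
    after = t > light_off_time_s
    if not after.any():
        raise CoverageError("no pulses after light-off")
    dt = np.abs(t[after] - relax_read_time_s)
    if dt.min() > tolerance_s:
        raise CoverageError(
            f"no pulse within +/-{tolerance_s} s of the relaxation read time "
            f"{relax_read_time_s} s"
        )
    npq_relaxed = float(npq[after][np.argmin(dt)])
    qe = npq_end_light - npq_relaxed
    return npq_end_light, npq_relaxed, qe, npq_relaxed
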