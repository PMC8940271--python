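"""Electrochromic-shift (ECS) analysis.

The carotenoid electrochromic bandshift at 520 nm reports the thylakoid
transmembrane potential linearly. After subtracting the 546-nm reference,
two primitives turn ECS kinetics into photochemistry:

* the signal 140 us after a saturating single-turnover flash calibrates
  one charge separation per photosystem (the flash fires every reaction
  center exactly once);
* the initial slope of the ECS decay after switching light off is
  proportional to the rate of PSI + PSII photochemistry, because reaction
  centers stop instantly while ATP-synthase consumption continues.

Dividing the slope by the one-charge amplitude gives the photochemical
rate in electrons per second per photosystem. With PSII inhibited (DCMU +
hydroxylamine) the same measurements isolate PSI: the flash-amplitude
ratio yields the PSII/PSI reaction-center ratio, and the far-red off-decay
rate over the total rate yields the cyclic electron flow fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Trace
from .errors import (
    CoverageError,
    DomainError,
    InconsistencyError,
    MalformedInputError,
    ResolutionError,
)


@dataclass(frozen=True)
class EcsFlashCalibration:
    """One-charge-separation calibration of the ECS signal.

    ``amp_one_charge`` is the -dI/I amplitude read ``read_delay_s`` after a
    saturating single-turnover flash with PSII inhibited (one charge per
    photosystem)."""

    amp_one_charge: float
    read_delay_s: float = 140e-6

    def __post_init__(self) -> None:
        if not self.amp_one_charge > 0:
            raise DomainError(
                f"amp_one_charge must be > 0, got {self.amp_one_charge}"
            )


@dataclass(frozen=True)
class PhotochemistryRecord:
    """Per-photosystem rates and derived stoichiometry of one sample."""

    rate_psii: float       # e- s-1 PSII-1
    rate_psi: float        # e- s-1 PSI-1
    r_psii_psi: float      # PSII/PSI reaction-center ratio
    cef_fraction: float    # percent of total electron flow
    chl_fraction_psi: float  # PSI share of total chlorophyll

    def __post_init__(self) -> None:
        if self.rate_psii < 0 or self.rate_psi < 0:
            raise DomainError("rates must be >= 0")
        if not self.r_psii_psi > 0:
            raise DomainError("r_psii_psi must be > 0")
        if not 0 <= self.cef_fraction <= 100:
            raise DomainError("cef_fraction must be in [0, 100]")


def deconvolve_ecs(trace_520: Trace, trace_546: Trace,
                   resample: bool = False) -> Trace:
    """Pointwise 520 - 546 nm difference, removing the non-electrochromic
    background. Time bases must match to 1e-9 s per sample unless
    ``resample`` linearly interpolates the 546-nm channel."""
    if len(trace_520.time) != len(trace_546.time) or not np.allclose(
        trace_520.time, trace_546.time, rtol=0.0, atol=1e-9
    ):
        if not resample:
            raise MalformedInputError(
                "520/546 time bases differ; pass resample=True to interpolate"
            )
        v546 = np.interp(trace_520.time, trace_546.time, trace_546.values)
    else:
        v546 = trace_546.values
    return Trace(
        time=trace_520.time.copy(),
        values=trace_520.values - v546,
        channel="ecs_corrected",
        meta={**trace_520.meta, "corrected_against": "ecs_546"},
    )


def flash_amplitude(
    trace: Trace,
    flash_time_s: float,
    read_delay_s: float = 140e-6,
    baseline_s: float = 1e-3,
) -> float:
    """ECS amplitude at ``flash_time + read_delay`` minus the pre-flash
    baseline (mean of ``baseline_s`` before the flash), with linear
    interpolation at the read time."""
    t0, t1 = trace.span
    read_t = flash_time_s + read_delay_s
    if flash_time_s - baseline_s < t0 or read_t + 9 * read_delay_s > t1:
        raise CoverageError(
            f"trace [{t0}, {t1}] does not cover the flash window around "
            f"{flash_time_s} s"
        )
    base_mask = (trace.time >= flash_time_s - baseline_s) & (
        trace.time < flash_time_s
    )
    if not base_mask.any():
        raise ResolutionError("no samples in the pre-flash baseline window")
    baseline = float(np.mean(trace.values[base_mask]))
    return trace.value_at(read_t) - baseline


def initial_slope(
    trace: Trace,
    event_time_s: float,
    window_s: float = 5e-3,
    side: str = "after",
) -> float:
    """Ordinary-least-squares slope (signal per second) over a short window
    on one side of an event. The window must stay well below the ECS decay
    time constant for the initial-slope approximation to hold."""
    if side == "after":
        mask = (trace.time >= event_time_s) & (
            trace.time < event_time_s + window_s
        )
    elif side == "before":
        mask = (trace.time >= event_time_s - window_s) & (
            trace.time < event_time_s
        )
    else:
        raise DomainError(f"side must be 'before' or 'after', got {side!r}")
    t = trace.time[mask]
    v = trace.values[mask]
    if len(t) < 4:
        raise ResolutionError(
            f"only {len(t)} samples in the {window_s} s window {side} "
            f"{event_time_s} s (need >= 4)"
        )
    slope, _ = np.polyfit(t, v, 1)
    return float(slope)


def photochemical_rate(slope: float, calibration: EcsFlashCalibration) -> float:
    """Electrons per second per photosystem: |slope| / one-charge amplitude."""
    return abs(slope) / calibration.amp_one_charge


def psii_psi_ratio(amp_flash_total: float, amp_flash_psi_only: float) -> float:
    """PSII/PSI reaction-center ratio from single-turnover flash amplitudes
    with and without PSII inhibition:
    r = (amp_total - amp_psi_only) / amp_psi_only."""
    if amp_flash_total <= 0 or amp_flash_psi_only <= 0:
        raise DomainError("flash amplitudes must be > 0")
    if amp_flash_total < amp_flash_psi_only:
        raise InconsistencyError(
            f"total-flash amplitude {amp_flash_total} below PSI-only "
            f"amplitude {amp_flash_psi_only}"
        )
    return (amp_flash_total - amp_flash_psi_only) / amp_flash_psi_only


def cef_fraction(rate_farred: float, rate_total: float) -> float:
    """Cyclic electron flow as a percentage of total electron flow."""
    if rate_total <= 0:
        raise DomainError("rate_total must be > 0")
    if rate_farred < 0:
        raise DomainError("rate_farred must be >= 0")
    if rate_farred > rate_total:
        raise InconsistencyError(
            f"far-red rate {rate_farred} exceeds total rate {rate_total}"
        )
    return 100.0 * rate_farred / rate_total
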