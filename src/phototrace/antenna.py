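"""Chlorophyll repartition between photosystems and PSII antenna sizing.

Three independent routes to the PSI share of total chlorophyll:

* rates + stoichiometry: under fixed light the per-photosystem
  photochemical rate is proportional to the per-photosystem absorption
  cross-section, and the PSII pool is r times the PSI pool, so
  PSI / (PSI + PSII) = rate_PSI / (rate_PSI + rate_PSII * r);
* FLIM: the amplitude a1 of the fast (~100 ps) fluorescence-decay
  component reports PSI-associated chlorophyll,
  PSI / (PSI + PSII) = c * a1 / (1 - a1 + c * a1), with c a
  setup-specific correction factor (default 0.49);
* DCMU induction: with PSII photochemistry blocked after a single stable
  charge separation, the reciprocal of the complementary area above the
  normalized fluorescence induction curve is the maximal initial PSII
  rate, proportional to the functional PSII antenna cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .core_io import Trace
from .errors import (
    CoverageError,
    DegenerateDataError,
    DomainError,
    MalformedInputError,
)

#: fixed decay lifetimes (ns) of the three-exponential fluorescence model
DEFAULT_LIFETIMES_NS = (0.1, 0.9, 2.0)
#: setup correction factor mapping a1 to a chlorophyll fraction
DEFAULT_C_FACTOR = 0.49


def exp_gauss_decay(t: np.ndarray, tau: float, sigma: float,
                    t0: float = 0.0) -> np.ndarray:
    """Exponential decay exp(-(t-t0)/tau) convolved with a Gaussian
    instrument response of width ``sigma`` (exponentially modified
    Gaussian, exact closed form). ``sigma = 0`` gives the pure truncated
    exponential."""
    t = np.asarray(t, dtype=float)
    if sigma <= 0:
        return np.where(t >= t0, np.exp(-np.maximum(t - t0, 0.0) / tau), 0.0)
    arg = (sigma / tau - (t - t0) / sigma) / np.sqrt(2.0)
    # log-space evaluation avoids overflow of exp(sigma^2 / 2 tau^2)
    log_pre = sigma**2 / (2 * tau**2) - (t - t0) / tau
    return 0.5 * np.exp(log_pre + np.log(np.maximum(special.erfc(arg), 1e-300)))


@dataclass(frozen=True)
class FlimFit:
    """Three-exponential fit of a TCSPC decay with fixed lifetimes."""

    amps: tuple[float, float, float]
    lifetimes_ns: tuple[float, float, float] = DEFAULT_LIFETIMES_NS
    chi2_reduced: float = float("nan")
    c_factor: float = DEFAULT_C_FACTOR

    def __post_init__(self) -> None:
        amps = np.asarray(self.amps, dtype=float)
        if (amps < 0).any() or abs(amps.sum() - 1.0) > 1e-9:
            raise DomainError("amplitudes must be non-negative and sum to 1")
        if not self.c_factor > 0:
            raise DomainError("c_factor must be > 0")

    @property
    def a1(self) -> float:
        return self.amps[0]


def chl_fraction_from_rates(rate_psi: float, rate_psii: float,
                            r_psii_psi: float) -> float:
    """PSI share of total chlorophyll from per-photosystem photochemical
    rates and the PSII/PSI reaction-center ratio:
    rate_PSI / (rate_PSI + rate_PSII * r)."""
    if rate_psi <= 0 or rate_psii <= 0 or r_psii_psi <= 0:
        raise DomainError("rates and reaction-center ratio must be > 0")
    return rate_psi / (rate_psi + rate_psii * r_psii_psi)


def fit_flim_decay(
    decay: Trace,
    lifetimes_ns=DEFAULT_LIFETIMES_NS,
    irf_sigma_ps: float = 0.0,
    c_factor: float = DEFAULT_C_FACTOR,
) -> FlimFit:
    """Fit a TCSPC histogram with fixed-lifetime exponentials.

    With the lifetimes fixed the fit is a linear non-negative
    least-squares problem on the (optionally IRF-convolved) basis,
    weighted by the Poisson uncertainty 1/sqrt(max(count, 1)). Amplitudes
    are normalized to sum to one; the reduced chi-square uses the same
    Poisson weights.
    """
    if decay.channel != "tcspc":
        raise MalformedInputError("FLIM fitting expects a tcspc trace")
    counts = decay.values
    if len(counts) < 50:
        raise CoverageError(f"decay has {len(counts)} bins (< 50)")
    if counts.sum() < 1e4:
        raise CoverageError(
            f"decay holds {counts.sum():.0f} photons (< 1e4); fit unreliable"
        )
    taus = np.asarray(lifetimes_ns, dtype=float) * 1e-9
    if len(np.unique(taus)) != len(taus):
        raise DomainError("lifetimes must be distinct")
    t0 = float(decay.meta.get("t0_s", 0.0))
    sigma = irf_sigma_ps * 1e-12
    basis = np.column_stack([
        exp_gauss_decay(decay.time, tau, sigma, t0) for tau in taus
    ])
    w = 1.0 / np.sqrt(np.maximum(counts, 1.0))
    coef, _ = optimize.nnls(basis * w[:, None], counts * w)
    if coef.sum() == 0:
        raise DegenerateDataError("all fitted amplitudes are zero")
    model = basis @ coef
    dof = max(len(counts) - len(taus), 1)
    chi2 = float(np.sum(((counts - model) * w) ** 2) / dof)
    amps = coef / coef.sum()
    return FlimFit(amps=tuple(amps), lifetimes_ns=tuple(lifetimes_ns),
                   chi2_reduced=chi2, c_factor=c_factor)


def psi_fraction_from_flim(a1: float, c_factor: float = DEFAULT_C_FACTOR) -> float:
    """PSI chlorophyll share from the fast FLIM amplitude:
    c * a1 / (1 - a1 + c * a1). Strictly increasing in a1."""
    if not 0 <= a1 <= 1:
        raise DomainError(f"a1 must be in [0, 1], got {a1}")
    if not c_factor > 0:
        raise DomainError("c_factor must be > 0")
    return c_factor * a1 / (1.0 - a1 + c_factor * a1)


def a1_from_psi_fraction(fraction: float,
                         c_factor: float = DEFAULT_C_FACTOR) -> float:
    """Analytic inverse of :func:`psi_fraction_from_flim` on [0, 1]."""
    if not 0 <= fraction <= 1:
        raise DomainError(f"fraction must be in [0, 1], got {fraction}")
    return fraction / (c_factor + fraction * (1.0 - c_factor))


def functional_antenna_dcmu(induction: Trace, f0: float, fm: float,
                            plateau_fraction: float = 0.99,
                            tail_fraction: float = 0.10) -> float:
    """Maximal initial PSII rate from a DCMU fluorescence induction curve.

    The curve is normalized to V(t) = (F(t) - F0) / (Fm - F0); the rate is
    the reciprocal of the complementary area integral(1 - V) dt, computed
    by trapezoids over the trace plus an analytic exponential-tail
    correction fitted to the last ``tail_fraction`` of samples.
    """
    if fm <= f0:
        raise DomainError(f"fm ({fm}) must exceed f0 ({f0})")
    t = induction.time - induction.time[0]
    v = (induction.values - f0) / (fm - f0)
    if v.max() < plateau_fraction:
        raise CoverageError(
            f"induction reaches only {v.max():.3f} of Fm "
            f"(< {plateau_fraction}); partial complementary area = "
            f"{np.trapezoid(1.0 - v, t):.4g} s"
        )
    area = float(np.trapezoid(1.0 - v, t))
    # exponential tail beyond the trace end: fit log(1 - V) on the last
    # samples that are still strictly below the plateau
    n_tail = max(int(len(t) * tail_fraction), 4)
    tt, cv = t[-n_tail:], 1.0 - v[-n_tail:]
    ok = cv > 0
    if ok.sum() >= 4:
        slope, intercept = np.polyfit(tt[ok], np.log(cv[ok]), 1)
        if slope < 0:
            tau = -1.0 / slope
            area += float(np.exp(intercept + slope * t[-1]) * tau)
    if area <= 0:
        raise DegenerateDataError("non-positive complementary area")
    return 1.0 / area
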