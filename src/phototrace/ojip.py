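"""Fast fluorescence induction (OJIP) and plastoquinone-pool reoxidation.

Vj is the relative variable fluorescence 3 ms into a saturating pulse,
(F(3 ms) - F0) / (Fm - F0); it tracks the redox state of the Q_B /
plastoquinone acceptor side of PSII. Plotting Vj against the dark or
far-red interval separating successive pulses quantifies how fast the
pool reoxidizes between pulses: far-red light excites PSI preferentially
and drains the pool faster, so the far-red series declines more steeply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_io import Trace
from .errors import CoverageError, DegenerateDataError, DomainError

#: delay after pulse onset at which F0 is read (first reliable point of
#: fast-induction instruments)
F0_READ_DELAY_S = 50e-6
#: the J step of the OJIP transient
VJ_READ_DELAY_S = 3e-3


@dataclass(frozen=True)
class VjTrend:
    """OLS trend of Vj against log10(interval), plus a LOWESS display curve."""

    slope: float          # Vj change per decade of interval
    intercept: float
    curve: pd.DataFrame   # (interval_s, vj_fit), for display only


def compute_vj(
    ojip: Trace,
    pulse_start_s: float,
    pulse_duration_s: float = 0.7,
    normalization: str = "variable",
) -> float:
    """Relative variable fluorescence at 3 ms of a fast induction pulse.

    F0 is read ``F0_READ_DELAY_S`` after pulse onset (interpolated), Fm is
    the maximum during the pulse. ``normalization="variable"`` returns
    (F(3ms) - F0)/(Fm - F0); ``"fm"`` returns the simpler F(3ms)/Fm.
    """
    t0, t1 = ojip.span
    end = pulse_start_s + pulse_duration_s
    if pulse_start_s < t0 or end > t1 + 1e-12:
        raise CoverageError(
            f"trace [{t0}, {t1}] does not cover the pulse "
            f"[{pulse_start_s}, {end}]"
        )
    mask = (ojip.time >= pulse_start_s) & (ojip.time < end)
    fm = float(np.max(ojip.values[mask]))
    f0 = ojip.value_at(pulse_start_s + F0_READ_DELAY_S)
    f_j = ojip.value_at(pulse_start_s + VJ_READ_DELAY_S)
    if normalization == "fm":
        if fm == 0:
            raise DegenerateDataError("Fm is zero")
        return f_j / fm
    if fm == f0:
        raise DegenerateDataError("Fm equals F0: no variable fluorescence")
    return (f_j - f0) / (fm - f0)


def fit_vj_trend(series: pd.DataFrame, lowess_span: float = 0.75) -> VjTrend:
    """Slope of Vj versus log10(interval_s) by ordinary least squares.

    The intervals of a pulse train span orders of magnitude (0.05-24 s),
    so the abscissa is log-transformed. A LOWESS curve (span 0.75) is
    returned alongside for display, mirroring the local-regression
    presentation customary for these series.
    """
    d = series["interval_s"].to_numpy(dtype=float)
    vj = series["vj"].to_numpy(dtype=float)
    if len(d) < 4:
        raise CoverageError(f"need >= 4 points, got {len(d)}")
    if (d <= 0).any():
        raise DomainError("intervals must be > 0 (log abscissa)")
    x = np.log10(d)
    slope, intercept = np.polyfit(x, vj, 1)
    smooth = sm.nonparametric.lowess(vj, x, frac=lowess_span, return_sorted=True)
    curve = pd.DataFrame({"interval_s": 10.0 ** smooth[:, 0],
                          "vj_fit": smooth[:, 1]})
    return VjTrend(slope=float(slope), intercept=float(intercept), curve=curve)
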