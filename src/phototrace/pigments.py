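"""Chlorophyll a/b quantification from extract absorbances.

Multi-wavelength quantification in Tris-buffered 80% acetone: the
absorbances at the chlorophyll a and b red maxima (663.6 and 646.6 nm,
1-cm pathlength) map linearly to concentrations,

    chl_a = 12.25 * A663.6 - 2.55 * A646.6   (ug/ml)
    chl_b = 20.31 * A646.6 - 4.91 * A663.6

after subtracting the 750-nm turbidity reading and scaling by the
dilution factor. The coefficient pairs are exposed as module constants so
other solvent systems can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError, InconsistencyError

#: buffered 80%-acetone coefficients: chl_a = A_COEF . (A663.6, A646.6)
CHL_A_COEF = (12.25, -2.55)
CHL_B_COEF = (-4.91, 20.31)
#: tolerance below zero before a concentration is declared inconsistent
NEGATIVE_TOLERANCE = 0.01


@dataclass(frozen=True)
class PigmentSample:
    """Absorbance readings of one chlorophyll extract."""

    a663_6: float
    a646_6: float
    a750: float = 0.0              # turbidity reference, subtracted
    dilution_factor: float = 1.0
    extract_volume_ml: float = 1.0
    fresh_weight_mg: float = 1.0

    def __post_init__(self) -> None:
        if self.a663_6 - self.a750 < 0 or self.a646_6 - self.a750 < 0:
            raise DomainError("turbidity-corrected absorbances must be >= 0")
        if self.dilution_factor < 1:
            raise DomainError("dilution_factor must be >= 1")
        if not self.fresh_weight_mg > 0:
            raise DomainError("fresh_weight_mg must be > 0")


def chl_from_absorbance(sample: PigmentSample) -> tuple[float, float]:
    """Chlorophyll a and b concentrations (ug/ml) from extract absorbances.

    Values in [-NEGATIVE_TOLERANCE, 0] are clamped to 0 (numerical noise);
    anything more negative indicates inconsistent spectra and raises.
    """
    a663 = (sample.a663_6 - sample.a750) * sample.dilution_factor
    a646 = (sample.a646_6 - sample.a750) * sample.dilution_factor
    chl_a = CHL_A_COEF[0] * a663 + CHL_A_COEF[1] * a646
    chl_b = CHL_B_COEF[0] * a663 + CHL_B_COEF[1] * a646
    out = []
    for name, v in (("chl_a", chl_a), ("chl_b", chl_b)):
        if v < -NEGATIVE_TOLERANCE:
            raise InconsistencyError(
                f"{name} = {v:.4g} ug/ml: absorbances inconsistent with "
                "a chlorophyll spectrum"
            )
        out.append(max(v, 0.0))
    return out[0], out[1]


def chl_per_fresh_weight(chl_a: float, chl_b: float, extract_volume_ml: float,
                         fresh_weight_mg: float) -> float:
    """Total chlorophyll normalized to fresh weight (ug chl per mg FW)."""
    if extract_volume_ml <= 0 or fresh_weight_mg <= 0:
        raise DomainError("volume and fresh weight must be > 0")
    return (chl_a + chl_b) * extract_volume_ml / fresh_weight_mg


def chl_ab_ratio(chl_a: float, chl_b: float) -> float:
    """Chlorophyll a/b ratio; an antenna-depletion indicator (LHCII binds
    most of the chlorophyll b)."""
    if chl_b <= 0:
        raise DomainError(f"chl_b must be > 0, got {chl_b}")
    return chl_a / chl_b
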