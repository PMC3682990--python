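"""Unit conversions used to assemble kinetic parameters from heterogeneous sources.

The pharmacological literature reports insulin aggregation coefficients in
``ml^2/U^2`` (clinical units of insulin activity), while the kinetic model
works throughout in molar concentrations (``pmol/L``, i.e. pM).  The bridge
between the two systems is a single conversion factor: 1 U/ml corresponds to
6.94e6 pM (equivalently, 1 uU/ml = 6.94 pM).  This is the convention under
which the published aggregation-coefficient tables for the Semilente,
Actrapid and Lispro formulations are mutually consistent to printed rounding.

The module also provides the elementary half-life -> first-order rate
conversion used for insulin degradation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ConversionFactor",
    "INSULIN_U_PER_ML_IN_PM",
    "DEFAULT_CONVERSION",
    "aggregation_coeff_to_si",
    "aggregation_coeff_from_si",
    "rate_from_half_life",
]


@dataclass(frozen=True)
class ConversionFactor:
    """Activity-to-molar bridge for insulin.

    Attributes
    ----------
    pmol_per_liter_per_U_per_ml:
        How many pM (pmol/L) correspond to a concentration of 1 U/ml.
    """

    pmol_per_liter_per_U_per_ml: float

    def __post_init__(self) -> None:
        if not self.pmol_per_liter_per_U_per_ml > 0:
            raise ValueError(
                "conversion factor must be strictly positive, got "
                f"{self.pmol_per_liter_per_U_per_ml!r}"
            )


#: 1 U/ml of insulin activity expressed in pM.
INSULIN_U_PER_ML_IN_PM = 6.94e6

DEFAULT_CONVERSION = ConversionFactor(INSULIN_U_PER_ML_IN_PM)


def aggregation_coeff_to_si(
    value: float, factor: ConversionFactor = DEFAULT_CONVERSION
) -> float:
    """Convert a dimer->hexamer aggregation coefficient from ``ml^2/U^2`` to ``L^2/pmol^2``.

    The coefficient multiplies a squared concentration, so it scales with the
    inverse square of the concentration conversion factor.

    Parameters
    ----------
    value:
        Aggregation coefficient in ``ml^2/U^2``; must be nonnegative.
    factor:
        Activity-to-molar conversion, in (pmol/L) per (U/ml).

    Returns
    -------
    float
        The coefficient in ``L^2/pmol^2``.
    """
    if value < 0:
        raise ValueError(f"aggregation coefficient must be nonnegative, got {value!r}")
    return value / factor.pmol_per_liter_per_U_per_ml**2


def aggregation_coeff_from_si(
    value: float, factor: ConversionFactor = DEFAULT_CONVERSION
) -> float:
    """Inverse of :func:`aggregation_coeff_to_si` (``L^2/pmol^2`` -> ``ml^2/U^2``)."""
    if value < 0:
        raise ValueError(f"aggregation coefficient must be nonnegative, got {value!r}")
    return value * factor.pmol_per_liter_per_U_per_ml**2


def rate_from_half_life(t_half: float) -> float:
    """First-order rate constant (min^-1) from a half-life in minutes.

    Exponential decay at rate ``ln(2)/t_half`` halves in exactly ``t_half``.
    """
    if not t_half > 0:
        raise ValueError(f"half-life must be strictly positive, got {t_half!r}")
    return math.log(2.0) / t_half
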