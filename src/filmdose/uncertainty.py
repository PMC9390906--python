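"""Per-dose uncertainty budget by first-order error propagation.

Two sources enter the film-dose uncertainty: the densitometer readout
(experimental) and the calibration fit (fitting).  With the cubic
dose(OD) = a*OD^3 + b*OD^2 + c*OD + d:

    delta_e = |3a*OD^2 + 2b*OD + c| * delta_OD
    delta_f = sqrt(sd_a^2*OD^6 + sd_b^2*OD^4 + sd_c^2*OD^2 + sd_d^2)
    delta_total = sqrt(delta_e^2 + delta_f^2)

delta_OD is the standard deviation of a single OD reading; a 2-decimal
display motivates the 0.01 OD default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .calibration import DENSITOMETER_PRECISION, CalibrationCurve, od_to_dose
from .exceptions import ConfigurationError, InvalidReadingError

__all__ = [
    "DensitometerModel",
    "UncertaintyBudget",
    "experimental_uncertainty",
    "fitting_uncertainty",
    "total_uncertainty",
    "dose_uncertainty_budget",
]


@dataclass(frozen=True)
class DensitometerModel:
    """Readout model of the point densitometer.

    ``delta_od`` is the standard deviation assigned to one OD reading
    (default: one display quantum, 0.01 OD); ``precision`` is the readout
    quantum itself.
    """

    delta_od: float = 0.01
    precision: float = DENSITOMETER_PRECISION

    def __post_init__(self) -> None:
        if self.delta_od < 0:
            raise InvalidReadingError(f"delta_od must be >= 0, got {self.delta_od}")
        if self.precision <= 0:
            raise InvalidReadingError(f"precision must be > 0, got {self.precision}")


@dataclass(frozen=True)
class UncertaintyBudget:
    """Uncertainty budget for one film dose (all dose terms in cGy)."""

    od: float
    dose: float
    delta_e: float
    delta_f: float
    delta_total: float

    @property
    def percent(self) -> float:
        """Total uncertainty as a percentage of dose (dose > 0 only)."""
        if self.dose <= 0:
            raise ZeroDivisionError(
                "percent uncertainty is defined only for positive dose"
            )
        return 100.0 * self.delta_total / self.dose


def experimental_uncertainty(
    curve: CalibrationCurve, od: float, dens: DensitometerModel
) -> float:
    """Densitometer contribution |d(dose)/d(OD)| * delta_OD in cGy."""
    if od < 0:
        raise InvalidReadingError(f"od must be >= 0, got {od}")
    return abs(curve.derivative(od)) * dens.delta_od


def fitting_uncertainty(curve: CalibrationCurve, od: float) -> float:
    """Calibration-fit contribution propagated from coefficient SDs (cGy)."""
    if od < 0:
        raise InvalidReadingError(f"od must be >= 0, got {od}")
    sds = curve.coefficient_sds
    if sds is None:
        raise ConfigurationError(
            "curve has no coefficient standard deviations; fit it with "
            "fit_calibration or supply sd_a..sd_d"
        )
    sd_a, sd_b, sd_c, sd_d = sds
    return math.sqrt(
        sd_a**2 * od**6 + sd_b**2 * od**4 + sd_c**2 * od**2 + sd_d**2
    )


def total_uncertainty(delta_e: float, delta_f: float) -> float:
    """Quadrature sum of the experimental and fitting contributions (cGy)."""
    if delta_e < 0 or delta_f < 0:
        raise InvalidReadingError(
            f"uncertainties must be >= 0, got ({delta_e}, {delta_f})"
        )
    return math.hypot(delta_e, delta_f)


def dose_uncertainty_budget(
    curve: CalibrationCurve,
    ods: Iterable[float],
    dens: DensitometerModel | None = None,
) -> list[UncertaintyBudget]:
    """Evaluate the full budget at each OD (requires fitted coefficient SDs)."""
    dens = dens or DensitometerModel()
    budgets = []
    for od in ods:
        de = experimental_uncertainty(curve, od, dens)
        df = fitting_uncertainty(curve, od)
        budgets.append(
            UncertaintyBudget(
                od=od,
                dose=od_to_dose(curve, od),
                delta_e=de,
                delta_f=df,
                delta_total=total_uncertainty(de, df),
            )
        )
    return budgets
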