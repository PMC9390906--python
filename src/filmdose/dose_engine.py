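"""Entrance-dose and skin-dose estimation for a surface film.

The entrance dose is the dose at the depth of maximum dose (Dmax, 0.5 cm for
Co-60).  A film on the patient surface reads only the build-up-depleted
surface dose, so a dimensionless entrance calibration factor

    Fcal_entrance = Ric / Rf              (reference conditions)

converts the film dose Df to the entrance dose together with the product of
correction factors:

    D_entrance = Df * Fcal_entrance * PiCF

Dose at depth follows from the percentage-depth-dose (PDD) table, and the
skin dose at the 0.070 mm basal-layer reference depth from a skin calibration
factor obtained by linearly extrapolating the optical density measured at the
film's active-layer depth (0.080 mm for a single film, 0.935 mm at the bottom
of a four-film stack):

    D_skin = Df * Fcal_skin
    % skin dose = 100 * Fcal_skin / (Fcal_entrance * PiCF)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    DENSITOMETER_PRECISION,
    CalibrationCurve,
    od_to_dose,
    quantize_od,
)
from .exceptions import FilmDoseError, InvalidReadingError, OutOfRangeError

#: Depth of maximum dose for a Co-60 beam (cm).
CO60_DMAX_CM = 0.5

#: Skin-dose reference depth: the radiosensitive basal layer (mm).
SKIN_REFERENCE_DEPTH_MM = 0.070

#: Depth of the active layer for a single film and for the bottom film of a
#: four-film stack (mm).
SINGLE_FILM_ACTIVE_DEPTH_MM = 0.080
FOUR_FILM_STACK_ACTIVE_DEPTH_MM = 0.935


@dataclass(frozen=True)
class CalibrationFactors:
    """Entrance and skin calibration factors (dimensionless)."""

    fcal_entrance: float
    fcal_skin: float = 1.0

    def __post_init__(self) -> None:
        if self.fcal_entrance <= 0 or self.fcal_skin <= 0:
            raise InvalidReadingError(
                f"calibration factors must be > 0, got "
                f"({self.fcal_entrance}, {self.fcal_skin})"
            )


@dataclass(frozen=True)
class DoseEstimate:
    """Per-film dose summary (doses in cGy, percentages on the 0-100 scale)."""

    df: float
    d_entrance: float
    d_skin: float | None = None
    prescribed: float | None = None

    @property
    def percent_skin(self) -> float | None:
        if self.d_skin is None or self.d_entrance == 0:
            return None
        return 100.0 * self.d_skin / self.d_entrance

    @property
    def percent_deviation(self) -> float | None:
        if self.prescribed is None:
            return None
        return 100.0 * abs(self.d_entrance - self.prescribed) / self.prescribed


@dataclass(frozen=True)
class DepthODPoint:
    """Optical density measured at a known active-layer depth (mm)."""

    depth: float  # mm
    od: float

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise InvalidReadingError(f"depth must be > 0 mm, got {self.depth}")


@dataclass(frozen=True)
class DepthDoseTable:
    """Percentage depth dose along the beam axis.

    ``knots`` are sorted (depth cm, PDD %) pairs with PDD = 100 at the depth
    of maximum dose.
    """

    knots: tuple[tuple[float, float], ...]
    dmax_depth: float = CO60_DMAX_CM

    def __post_init__(self) -> None:
        depths = [d for d, _ in self.knots]
        pdds = [p for _, p in self.knots]
        if any(d2 <= d1 for d1, d2 in zip(depths, depths[1:])):
            raise FilmDoseError("PDD knots must be strictly sorted by depth")
        if any(not 0 < p <= 100 + 1e-9 for p in pdds):
            raise FilmDoseError("PDD values must lie in (0, 100]")
        if abs(self.pdd(self.dmax_depth) - 100.0) > 1e-6:
            raise FilmDoseError(
                f"PDD must equal 100% at dmax_depth={self.dmax_depth} cm"
            )

    def pdd(self, depth: float) -> float:
        """Linearly interpolated PDD (%) at ``depth`` cm; no extrapolation."""
        depths = np.array([d for d, _ in self.knots])
        pdds = np.array([p for _, p in self.knots])
        if not depths[0] <= depth <= depths[-1]:
            raise OutOfRangeError(
                f"depth {depth} cm outside PDD table range "
                f"[{depths[0]}, {depths[-1]}]"
            )
        return float(np.interp(depth, depths, pdds))


def entrance_calibration_factor(ric: float, rf: float) -> float:
    """Fcal_entrance = Ric / Rf, both measured at reference conditions."""
    if rf <= 0 or ric <= 0:
        raise InvalidReadingError(
            f"reference readings must be > 0, got Ric={ric}, Rf={rf}"
        )
    return ric / rf


def entrance_dose(df: float, factors: CalibrationFactors, cf_product: float) -> float:
    """D_entrance = Df * Fcal_entrance * PiCF (cGy)."""
    if df < 0:
        raise InvalidReadingError(f"film dose must be >= 0, got {df}")
    if cf_product <= 0:
        raise InvalidReadingError(f"CF product must be > 0, got {cf_product}")
    return df * factors.fcal_entrance * cf_product


def dose_at_depth(d_entrance: float, table: DepthDoseTable, depth: float) -> float:
    """Dose at ``depth`` cm: entrance dose scaled by PDD(depth)/100."""
    return d_entrance * table.pdd(depth) / 100.0


def extrapolate_od_to_depth(
    p1: DepthODPoint, p2: DepthODPoint, target_depth: float
) -> tuple[float, float]:
    """Linearly extrapolate OD to ``target_depth`` mm from two depth points.

    Solves (d2 - d1)/(d2 - target) = (od2 - od1)/(od2 - x) for x, i.e. the
    straight line through the two depth/OD points evaluated at the target.
    Returns ``(raw, rounded)`` where ``rounded`` is quantised to the
    densitometer's 2-decimal display.
    """
    if p1.depth == p2.depth:
        raise FilmDoseError(
            f"cannot extrapolate from two points at the same depth {p1.depth} mm"
        )
    slope = (p2.od - p1.od) / (p2.depth - p1.depth)
    raw = p2.od - slope * (p2.depth - target_depth)
    return raw, quantize_od(raw, DENSITOMETER_PRECISION)


def skin_calibration_factor(
    od_at_skin_depth: float,
    od_at_film_depth: float,
    curve: CalibrationCurve,
    *,
    round_to_precision: bool = True,
) -> float:
    """Fcal_skin: film dose at 0.070 mm over film dose at the active layer.

    By default both ODs are first quantised to the densitometer's 2-decimal
    display, mirroring how the factor is determined from displayed readings
    (the two rounded ODs typically coincide, giving exactly 1.00);
    ``round_to_precision=False`` uses the raw extrapolated ODs instead.
    """
    if round_to_precision:
        od_at_skin_depth = quantize_od(od_at_skin_depth)
        od_at_film_depth = quantize_od(od_at_film_depth)
    numerator = od_to_dose(curve, od_at_skin_depth)
    denominator = od_to_dose(curve, od_at_film_depth)
    if denominator == 0:
        raise ZeroDivisionError(
            "film dose at the active-layer depth is zero; cannot form Fcal_skin"
        )
    return numerator / denominator


def skin_dose(df: float, fcal_skin: float) -> float:
    """D_skin = Df * Fcal_skin (cGy)."""
    if df < 0:
        raise InvalidReadingError(f"film dose must be >= 0, got {df}")
    return df * fcal_skin


def percent_skin_dose(
    fcal_entrance: float, cf_product: float, fcal_skin: float = 1.0
) -> float:
    """Skin dose as a percentage of the entrance dose.

    %skin = 100 * Fcal_skin / (Fcal_entrance * PiCF); the film dose cancels
    between numerator and denominator.
    """
    denominator = fcal_entrance * cf_product
    if denominator <= 0 or fcal_skin <= 0:
        raise ZeroDivisionError(
            f"factors must be > 0, got Fcal_entrance={fcal_entrance}, "
            f"PiCF={cf_product}, Fcal_skin={fcal_skin}"
        )
    return 100.0 * fcal_skin / denominator
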