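"""Optical-density handling and the cubic dose-calibration curve.

A radiochromic film darkens when irradiated; a point densitometer reports the
optical density (OD) before irradiation (``od_pre``) and after stabilisation
(``od_post``).  The dose signal is the net optical density

    NOD = od_post - od_pre

and absorbed dose follows from a third-degree polynomial calibrated against
ionisation-chamber measurements:

    dose(OD) = a*OD**3 + b*OD**2 + c*OD + d     [cGy]

All doses in this package are centigray.  The module fits the cubic by
unweighted least squares, reports coefficient standard deviations from the
ordinary-least-squares covariance, and inverts the curve by bisection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import (
    DomainError,
    DosimetryWarning,
    FitError,
    InvalidReadingError,
    MonotonicityError,
    OutOfRangeError,
)

#: Readout quantum of a 2-decimal point densitometer (OD units).
DENSITOMETER_PRECISION = 0.01

#: Grid size used for monotonicity checks on the calibration domain.
MONOTONICITY_GRID = 1000


def quantize_od(od: float, precision: float = DENSITOMETER_PRECISION) -> float:
    """Round an optical density to the densitometer's display precision."""
    return round(round(od / precision) * precision, 10)


def net_optical_density(od_pre: float, od_post: float) -> float:
    """Net optical density NOD = od_post - od_pre.

    Negative inputs are physical impossibilities and raise
    :class:`InvalidReadingError`; a negative *result* (post darker reading
    than pre) is allowed but flagged with a :class:`DosimetryWarning`.
    """
    if od_pre < 0 or od_post < 0:
        raise InvalidReadingError(
            f"optical densities must be non-negative, got od_pre={od_pre}, "
            f"od_post={od_post}"
        )
    nod = od_post - od_pre
    if nod < 0:
        warnings.warn(
            f"negative net optical density ({nod:.4f}): post-irradiation "
            "reading is lighter than the pre-irradiation baseline",
            DosimetryWarning,
            stacklevel=2,
        )
    return nod


@dataclass
class FilmReading:
    """One film's densitometer readings and derived net optical density."""

    film_id: str
    od_pre: float
    od_post: float
    encapsulated: bool = False
    nod: float = field(init=False)

    def __post_init__(self) -> None:
        for name, value in (("od_pre", self.od_pre), ("od_post", self.od_post)):
            if not 0 <= value < 4:
                raise InvalidReadingError(
                    f"{name}={value} outside the physical range [0, 4) "
                    f"for film {self.film_id!r}"
                )
        self.nod = net_optical_density(self.od_pre, self.od_post)


@dataclass(frozen=True)
class CalibrationPoint:
    """A (net optical density, chamber dose) pair used for calibration."""

    nod: float
    dose: float  # cGy, ionisation-chamber reference

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise InvalidReadingError(f"calibration dose must be >= 0, got {self.dose}")


def _check_monotone(coeffs: Sequence[float], od_domain: tuple[float, float]) -> None:
    lo, hi = od_domain
    grid = np.linspace(lo, hi, MONOTONICITY_GRID)
    values = np.polyval(coeffs, grid)
    if not np.all(np.diff(values) > 0):
        raise MonotonicityError(
            f"calibration polynomial is not strictly increasing on "
            f"[{lo}, {hi}]"
        )


@dataclass(frozen=True)
class CalibrationCurve:
    """Cubic OD→dose calibration curve with fit diagnostics.

    Coefficients follow dose = a*OD^3 + b*OD^2 + c*OD + d, doses in cGy.
    ``sd_a``..``sd_d`` are the coefficient standard deviations (None when the
    curve was written down rather than fitted); ``r_fit`` is the Pearson
    correlation between measured and fitted doses.
    """

    a: float
    b: float
    c: float
    d: float
    od_domain: tuple[float, float]
    sd_a: float | None = None
    sd_b: float | None = None
    sd_c: float | None = None
    sd_d: float | None = None
    r_fit: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.od_domain
        if lo < 0:
            raise DomainError(f"od_domain lower bound must be >= 0, got {lo}")
        if not hi > lo:
            raise DomainError(f"od_domain must be a non-empty interval, got {self.od_domain}")
        if self.r_fit is not None and not -1 <= self.r_fit <= 1 + 1e-12:
            raise FitError(f"r_fit must lie in [-1, 1], got {self.r_fit}")
        _check_monotone(self.coefficients, self.od_domain)

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        """(a, b, c, d) in descending powers, as consumed by np.polyval."""
        return (self.a, self.b, self.c, self.d)

    @property
    def coefficient_sds(self) -> tuple[float, ...] | None:
        sds = (self.sd_a, self.sd_b, self.sd_c, self.sd_d)
        return None if any(s is None for s in sds) else sds  # type: ignore[return-value]

    def derivative(self, od: float) -> float:
        """d(dose)/d(OD) at ``od`` (cGy per OD)."""
        return 3 * self.a * od**2 + 2 * self.b * od + self.c

    def dose_range(self) -> tuple[float, float]:
        """Attainable dose interval over the OD domain (curve is monotone)."""
        lo, hi = self.od_domain
        return (float(np.polyval(self.coefficients, lo)),
                float(np.polyval(self.coefficients, hi)))

    def to_json(self) -> str:
        payload = {
            "coefficients": {"a": self.a, "b": self.b, "c": self.c, "d": self.d},
            "coefficient_sds": {"sd_a": self.sd_a, "sd_b": self.sd_b,
                                 "sd_c": self.sd_c, "sd_d": self.sd_d},
            "od_domain": list(self.od_domain),
            "r_fit": self.r_fit,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationCurve":
        payload = json.loads(text)
        co = payload["coefficients"]
        sds = payload.get("coefficient_sds") or {}
        return cls(
            a=co["a"], b=co["b"], c=co["c"], d=co["d"],
            od_domain=tuple(payload["od_domain"]),
            sd_a=sds.get("sd_a"), sd_b=sds.get("sd_b"),
            sd_c=sds.get("sd_c"), sd_d=sds.get("sd_d"),
            r_fit=payload.get("r_fit"),
        )


#: Calibration curve measured for EBT2 film on a Co-60 teletherapy beam
#: with a 2-decimal point densitometer (coefficients in cGy per OD^k).  The
#: domain covers the 50-800 cGy calibration span of that measurement.
EBT2_CO60_CURVE = CalibrationCurve(
    a=1685.0, b=-187.9, c=1006.0, d=-2.328, od_domain=(0.0, 0.65)
)


def fit_calibration(points: Iterable[CalibrationPoint]) -> CalibrationCurve:
    """Fit the cubic calibration curve by unweighted least squares.

    Requires at least 5 points with at least 4 distinct NOD values (a cubic
    has 4 parameters).  Coefficient standard deviations come from the OLS
    covariance sigma^2 (X^T X)^-1 with sigma^2 = RSS / (n - 4); ``r_fit`` is
    the Pearson correlation between measured and fitted doses; the valid OD
    domain is [min NOD, max NOD].
    """
    pts = list(points)
    if len(pts) < 5:
        raise FitError(f"need >= 5 calibration points, got {len(pts)}")
    nod = np.array([p.nod for p in pts], dtype=float)
    dose = np.array([p.dose for p in pts], dtype=float)
    if len(np.unique(nod)) < 4:
        raise FitError(
            f"need >= 4 distinct NOD values to fit a cubic, got {len(np.unique(nod))}"
        )

    # Design matrix in descending powers: [OD^3, OD^2, OD, 1].
    X = np.vander(nod, 4)
    coeffs, _, rank, _ = np.linalg.lstsq(X, dose, rcond=None)
    if rank < 4:
        raise FitError("rank-deficient design: NOD values too degenerate for a cubic")

    fitted = X @ coeffs
    rss = float(np.sum((dose - fitted) ** 2))
    dof = len(pts) - 4
    sigma2 = rss / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    sds = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    if np.std(fitted) == 0 or np.std(dose) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(dose, fitted)[0, 1])

    return CalibrationCurve(
        a=float(coeffs[0]), b=float(coeffs[1]), c=float(coeffs[2]), d=float(coeffs[3]),
        od_domain=(float(nod.min()), float(nod.max())),
        sd_a=float(sds[0]), sd_b=float(sds[1]), sd_c=float(sds[2]), sd_d=float(sds[3]),
        r_fit=min(r, 1.0),
    )


def od_to_dose(
    curve: CalibrationCurve,
    od: float,
    *,
    strict: bool = False,
    clamp_negative: bool = False,
) -> float:
    """Evaluate the calibration polynomial at ``od`` (cGy).

    ``strict`` rejects ODs outside the curve's domain; otherwise out-of-domain
    evaluation proceeds (the cubic extrapolates smoothly near the domain).
    ``clamp_negative`` is a reporting convenience: negative raw doses are
    clamped to 0 with a warning.  By default the raw value is returned.
    """
    lo, hi = curve.od_domain
    if strict and not lo <= od <= hi:
        raise DomainError(f"OD {od} outside calibration domain [{lo}, {hi}]")
    dose = float(np.polyval(curve.coefficients, od))
    if dose < 0:
        if clamp_negative:
            warnings.warn(
                f"negative dose {dose:.4f} cGy at OD {od} clamped to 0 for reporting",
                DosimetryWarning,
                stacklevel=2,
            )
            return 0.0
        warnings.warn(
            f"negative dose {dose:.4f} cGy at OD {od}",
            DosimetryWarning,
            stacklevel=2,
        )
    return dose


def dose_to_od(curve: CalibrationCurve, dose: float, *, tol: float = 1e-9) -> float:
    """Invert the monotone calibration curve by bisection.

    Returns the unique OD on the curve's domain whose polynomial value is
    within ``tol`` cGy of ``dose``.
    """
    lo, hi = curve.od_domain
    f_lo, f_hi = curve.dose_range()
    if not f_lo - tol <= dose <= f_hi + tol:
        raise OutOfRangeError(
            f"dose {dose} cGy outside attainable range [{f_lo:.4f}, {f_hi:.4f}]"
        )
    coeffs = curve.coefficients
    a, b = lo, hi
    for _ in range(200):
        mid = 0.5 * (a + b)
        value = float(np.polyval(coeffs, mid))
        if abs(value - dose) < tol or (b - a) < 1e-16:
            return mid
        if value < dose:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)
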