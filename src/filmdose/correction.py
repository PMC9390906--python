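"""Correction factors for irradiation parameters and configuration comparisons.

A surface film over-responds to contaminating electrons whose yield depends on
field size, source-to-skin distance (SSD), gantry angle and wedge angle.  Each
parameter gets a correction factor measured against an ionisation chamber:

    CF = (Ric/Rf)_clinical / (Ric/Rf)_reference

normalised so CF = 1 at the reference condition (10 cm x 10 cm open field,
SSD 100 cm, gantry 0 deg).  Factors for a concrete treatment multiply into
PiCF.  Between measured settings CF is interpolated piecewise-linearly; the
measured grid is never extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    ExtrapolationError,
    FilmDoseError,
    InsufficientDataError,
    InvalidReadingError,
)

#: Canonical parameter names and their reference settings.
REFERENCE_CONDITIONS: dict[str, float] = {
    "field_size_cm": 10.0,
    "ssd_cm": 100.0,
    "gantry_deg": 0.0,
    "wedge_deg": 0.0,  # 0 == open field, no wedge
}


@dataclass(frozen=True)
class PairedReading:
    """Matched ionisation-chamber dose Ric and film dose Rf (both cGy)."""

    ric: float
    rf: float
    condition: tuple[str, float]  # (parameter name, parameter value)

    def __post_init__(self) -> None:
        if self.ric <= 0 or self.rf <= 0:
            raise InvalidReadingError(
                f"paired readings must be positive, got Ric={self.ric}, "
                f"Rf={self.rf} at {self.condition}"
            )

    @property
    def ratio(self) -> float:
        return self.ric / self.rf


def correction_factor(clinical: PairedReading, reference: PairedReading) -> float:
    """CF = (Ric/Rf at the clinical condition) / (Ric/Rf at reference)."""
    return clinical.ratio / reference.ratio


@dataclass(frozen=True)
class CorrectionFactorTable:
    """Correction factors tabulated along one irradiation parameter."""

    parameter: str
    knots: tuple[tuple[float, float], ...]  # sorted (parameter value, CF)
    reference_value: float

    def __post_init__(self) -> None:
        values = [v for v, _ in self.knots]
        cfs = [cf for _, cf in self.knots]
        if len(values) < 1:
            raise FilmDoseError(f"CF table for {self.parameter!r} has no knots")
        if any(v2 <= v1 for v1, v2 in zip(values, values[1:])):
            raise FilmDoseError(
                f"CF knots for {self.parameter!r} must be strictly sorted"
            )
        if any(cf <= 0 for cf in cfs):
            raise FilmDoseError(f"CF values for {self.parameter!r} must be > 0")
        if self.reference_value in values:
            ref_cf = cfs[values.index(self.reference_value)]
            if abs(ref_cf - 1.0) > 1e-9:
                raise FilmDoseError(
                    f"CF at the reference {self.parameter}="
                    f"{self.reference_value} must be 1.0, got {ref_cf}"
                )

    @classmethod
    def from_paired_readings(
        cls,
        parameter: str,
        readings: Iterable[PairedReading],
        reference_value: float | None = None,
    ) -> "CorrectionFactorTable":
        """Build a table from chamber/film pairs measured along one parameter.

        Repeated readings at a setting are pooled (mean Ric, mean Rf) before
        the ratio is taken; the table is normalised so that CF at the
        reference setting is exactly 1.
        """
        if reference_value is None:
            if parameter not in REFERENCE_CONDITIONS:
                raise FilmDoseError(
                    f"no default reference value for parameter {parameter!r}"
                )
            reference_value = REFERENCE_CONDITIONS[parameter]
        pooled: dict[float, list[PairedReading]] = {}
        for r in readings:
            name, value = r.condition
            if name != parameter:
                raise FilmDoseError(
                    f"reading for {name!r} passed to {parameter!r} table"
                )
            pooled.setdefault(value, []).append(r)
        if reference_value not in pooled:
            raise FilmDoseError(
                f"no reading at the reference {parameter}={reference_value}"
            )

        def pooled_ratio(rs: list[PairedReading]) -> float:
            return float(np.mean([r.ric for r in rs]) / np.mean([r.rf for r in rs]))

        ref_ratio = pooled_ratio(pooled[reference_value])
        knots = tuple(
            (value, pooled_ratio(rs) / ref_ratio)
            for value, rs in sorted(pooled.items())
        )
        return cls(parameter=parameter, knots=knots, reference_value=reference_value)

    def lookup(self, value: float) -> float:
        """Piecewise-linear CF at ``value``; exact at knots, no extrapolation."""
        values = np.array([v for v, _ in self.knots])
        cfs = np.array([cf for _, cf in self.knots])
        if not values[0] <= value <= values[-1]:
            raise ExtrapolationError(
                f"{self.parameter}={value} outside measured range "
                f"[{values[0]}, {values[-1]}]"
            )
        exact = np.nonzero(values == value)[0]
        if exact.size:
            return float(cfs[exact[0]])
        return float(np.interp(value, values, cfs))


def lookup_cf(table: CorrectionFactorTable, value: float) -> float:
    """Functional alias for :meth:`CorrectionFactorTable.lookup`."""
    return table.lookup(value)


@dataclass(frozen=True)
class CorrectionFactorSet:
    """One CF table per irradiation parameter; absent parameters contribute 1."""

    tables: Mapping[str, CorrectionFactorTable] = field(default_factory=dict)

    def product(self, conditions: Mapping[str, float]) -> float:
        """PiCF over the named conditions (empty set of conditions -> 1.0)."""
        result = 1.0
        for parameter, value in conditions.items():
            if parameter not in self.tables:
                raise FilmDoseError(
                    f"no correction-factor table for condition {parameter!r}"
                )
            result *= self.tables[parameter].lookup(value)
        return result


def product_cf(cf_set: CorrectionFactorSet, conditions: Mapping[str, float]) -> float:
    """Functional alias for :meth:`CorrectionFactorSet.product`."""
    return cf_set.product(conditions)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a paired comparison of two normalised response series."""

    statistic: float
    pvalue: float
    n: int
    alpha: float
    mean_difference: float
    test: str = "paired two-sided t-test"

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


def compare_configurations(
    series_a: Sequence[float],
    series_b: Sequence[float],
    *,
    paired: bool = True,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sided comparison of matched normalised film responses.

    The two series are responses of two film configurations (for example
    unencapsulated vs encapsulated) measured at the same settings, so the
    default is a paired t-test on the within-setting differences.  Two
    identical series yield statistic 0 and p = 1.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if paired and a.shape != b.shape:
        raise FilmDoseError(
            f"paired series must have equal lengths, got {a.size} and {b.size}"
        )
    n = int(a.size)
    if n < 3 or (not paired and b.size < 3):
        raise InsufficientDataError(
            f"need at least 3 observations per series, got {n}"
        )
    if paired:
        diffs = b - a
        if np.allclose(diffs, diffs[0]) and np.isclose(diffs[0], 0.0):
            return ComparisonResult(0.0, 1.0, n, alpha, 0.0)
        result = stats.ttest_rel(a, b)
        mean_diff = float(np.mean(diffs))
    else:
        result = stats.ttest_ind(a, b)
        mean_diff = float(np.mean(b) - np.mean(a))
    return ComparisonResult(
        statistic=float(result.statistic),
        pvalue=float(result.pvalue),
        n=n,
        alpha=alpha,
        mean_difference=mean_diff,
    )
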