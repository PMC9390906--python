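"""CSV dialects, run configuration, and the end-to-end report pipeline.

All files are plain CSV with a header row.  Units are embedded in column
names (``dose_cGy``, ``depth_cm``) to keep them unambiguous; depths are cm
except film-layer depths, which the protocol states in mm.

Dialects:

* film readings:        ``film_id,od_pre,od_post,encapsulated``
* calibration points:   ``nod,dose_cGy``
* CF measurements:      ``parameter,value,ric_cGy,rf_cGy``
* CF tables:            ``parameter,value,cf``
* PDD table:            ``depth_cm,pdd_percent``
* per-film report:      see :func:`run_pipeline`
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationCurve, FilmReading, CalibrationPoint, quantize_od
from .correction import (
    REFERENCE_CONDITIONS,
    CorrectionFactorSet,
    CorrectionFactorTable,
    PairedReading,
)
from .dose_engine import (
    CalibrationFactors,
    DepthDoseTable,
    entrance_dose,
    skin_dose,
)
from .uncertainty import (
    DensitometerModel,
    experimental_uncertainty,
    fitting_uncertainty,
    total_uncertainty,
)
from .exceptions import ConfigurationError, ParseError, PipelineError, SchemaError
from . import calibration

logger = logging.getLogger("filmdose")

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n", ""}


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    for column in required:
        if column not in df.columns:
            raise SchemaError(f"{path}: missing required column {column!r}")


def _numeric(df: pd.DataFrame, column: str, path: str) -> np.ndarray:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = converted.isna() & df[column].notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based, plus header row
        raise ParseError(
            f"{path}: non-numeric value {df[column][bad.idxmax()]!r} in column "
            f"{column!r} at row {row}"
        )
    if converted.isna().any():
        row = int(converted.isna().idxmax()) + 2
        raise ParseError(f"{path}: empty value in column {column!r} at row {row}")
    return converted.to_numpy(dtype=float)


def _parse_bool(value: object, path: str, row: int) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE or text == "nan":
        return False
    raise ParseError(f"{path}: cannot parse {value!r} as a flag at row {row}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_film_readings(
    path: str | Path, instrument_precision: bool = False
) -> list[FilmReading]:
    """Read a readings CSV; ``instrument_precision`` quantises ODs to 0.01."""
    path = str(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["film_id", "od_pre", "od_post"], path)
    od_pre = _numeric(df, "od_pre", path)
    od_post = _numeric(df, "od_post", path)
    if instrument_precision:
        od_pre = np.array([quantize_od(v) for v in od_pre])
        od_post = np.array([quantize_od(v) for v in od_post])
    encapsulated = (
        [_parse_bool(v, path, i + 2) for i, v in enumerate(df["encapsulated"])]
        if "encapsulated" in df.columns
        else [False] * len(df)
    )
    return [
        FilmReading(
            film_id=str(df["film_id"][i]),
            od_pre=float(od_pre[i]),
            od_post=float(od_post[i]),
            encapsulated=encapsulated[i],
        )
        for i in range(len(df))
    ]


def write_film_readings(readings: Iterable[FilmReading], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "film_id": r.film_id,
                "od_pre": r.od_pre,
                "od_post": r.od_post,
                "encapsulated": r.encapsulated,
            }
            for r in readings
        ]
    ).to_csv(path, index=False, float_format="%.17g")


def read_calibration_points(path: str | Path) -> list[CalibrationPoint]:
    path = str(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["nod", "dose_cGy"], path)
    nod = _numeric(df, "nod", path)
    dose = _numeric(df, "dose_cGy", path)
    return [CalibrationPoint(nod=float(n), dose=float(d)) for n, d in zip(nod, dose)]


def write_calibration_points(
    points: Iterable[CalibrationPoint], path: str | Path
) -> None:
    pd.DataFrame(
        [{"nod": p.nod, "dose_cGy": p.dose} for p in points]
    ).to_csv(path, index=False, float_format="%.17g")


def read_cf_measurements(path: str | Path) -> dict[str, list[PairedReading]]:
    """CF-measurement CSV → paired readings grouped by parameter."""
    path = str(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["parameter", "value", "ric_cGy", "rf_cGy"], path)
    value = _numeric(df, "value", path)
    ric = _numeric(df, "ric_cGy", path)
    rf = _numeric(df, "rf_cGy", path)
    grouped: dict[str, list[PairedReading]] = {}
    for i in range(len(df)):
        parameter = str(df["parameter"][i])
        grouped.setdefault(parameter, []).append(
            PairedReading(
                ric=float(ric[i]),
                rf=float(rf[i]),
                condition=(parameter, float(value[i])),
            )
        )
    return grouped


def write_cf_measurements(
    readings: Iterable[PairedReading], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "parameter": r.condition[0],
                "value": r.condition[1],
                "ric_cGy": r.ric,
                "rf_cGy": r.rf,
            }
            for r in readings
        ]
    ).to_csv(path, index=False, float_format="%.17g")


def write_cf_tables(cf_set: CorrectionFactorSet, path: str | Path) -> None:
    rows = [
        {"parameter": parameter, "value": value, "cf": cf}
        for parameter, table in cf_set.tables.items()
        for value, cf in table.knots
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_cf_tables(path: str | Path) -> CorrectionFactorSet:
    path = str(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["parameter", "value", "cf"], path)
    value = _numeric(df, "value", path)
    cf = _numeric(df, "cf", path)
    tables = {}
    for parameter in df["parameter"].unique():
        mask = (df["parameter"] == parameter).to_numpy()
        knots = sorted(zip(value[mask], cf[mask]))
        if parameter in REFERENCE_CONDITIONS:
            reference = REFERENCE_CONDITIONS[parameter]
        else:
            ones = [v for v, c in knots if abs(c - 1.0) < 1e-9]
            if not ones:
                raise SchemaError(
                    f"{path}: cannot infer reference value for {parameter!r}"
                )
            reference = ones[0]
        tables[str(parameter)] = CorrectionFactorTable(
            parameter=str(parameter),
            knots=tuple((float(v), float(c)) for v, c in knots),
            reference_value=float(reference),
        )
    return CorrectionFactorSet(tables=tables)


def read_pdd_table(path: str | Path, dmax_depth: float | None = None) -> DepthDoseTable:
    path = str(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["depth_cm", "pdd_percent"], path)
    depth = _numeric(df, "depth_cm", path)
    pdd = _numeric(df, "pdd_percent", path)
    knots = tuple(sorted(zip(depth, pdd)))
    if dmax_depth is None:
        at_max = [d for d, p in knots if abs(p - 100.0) < 1e-9]
        if not at_max:
            raise SchemaError(f"{path}: no knot with PDD = 100 to locate Dmax")
        dmax_depth = at_max[0]
    return DepthDoseTable(knots=knots, dmax_depth=float(dmax_depth))


def write_pdd_table(table: DepthDoseTable, path: str | Path) -> None:
    pd.DataFrame(
        [{"depth_cm": d, "pdd_percent": p} for d, p in table.knots]
    ).to_csv(path, index=False, float_format="%.17g")


def write_curve(curve: CalibrationCurve, path: str | Path) -> None:
    Path(path).write_text(curve.to_json())


def read_curve(path: str | Path) -> CalibrationCurve:
    return CalibrationCurve.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one in-vivo dosimetry run."""

    prescribed_cGy: float = 200.0
    conditions: dict[str, float] = dc_field(default_factory=dict)
    reference_conditions: dict[str, float] = dc_field(
        default_factory=lambda: dict(REFERENCE_CONDITIONS)
    )
    fcal_entrance: float = 4.134
    fcal_skin: float = 1.0
    delta_od: float = 0.01
    strict: bool = False
    skin_percent_decimals: int = 0
    deviation_decimals: int = 2
    curve_path: str | None = None
    cf_tables_path: str | None = None
    pdd_path: str | None = None

    def __post_init__(self) -> None:
        if self.prescribed_cGy <= 0:
            raise ConfigurationError(
                f"prescribed dose must be > 0, got {self.prescribed_cGy}"
            )
        if not self.reference_conditions:
            raise ConfigurationError("reference conditions must be present")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def run_pipeline(
    readings: Sequence[FilmReading],
    curve: CalibrationCurve,
    cf_set: CorrectionFactorSet,
    config: RunConfig,
    dens: DensitometerModel | None = None,
) -> pd.DataFrame:
    """Per-film dosimetry report: NOD → film dose → uncertainty budget →
    correction factors → entrance, skin and percentage doses.

    Every factor entering a derived value is itself a column, so any report
    row can be recomputed from its own logged inputs.  Fitting uncertainty is
    NaN when the curve carries no coefficient standard deviations (for
    example a transcribed rather than fitted curve).
    """
    dens = dens or DensitometerModel(delta_od=config.delta_od)
    factors = CalibrationFactors(
        fcal_entrance=config.fcal_entrance, fcal_skin=config.fcal_skin
    )
    try:
        cf_product = cf_set.product(config.conditions)
    except Exception as exc:
        raise PipelineError(f"[correction] {exc}") from exc
    logger.info(
        "pipeline: Fcal_entrance=%.4f Fcal_skin=%.4f PiCF=%.6f conditions=%s",
        factors.fcal_entrance, factors.fcal_skin, cf_product, config.conditions,
    )

    rows = []
    for reading in readings:
        try:
            df_dose = calibration.od_to_dose(curve, reading.nod, strict=config.strict)
        except Exception as exc:
            raise PipelineError(f"[calibration] film {reading.film_id!r}: {exc}") from exc
        try:
            delta_e = experimental_uncertainty(curve, reading.nod, dens)
            if curve.coefficient_sds is None:
                delta_f = float("nan")
                delta_total = delta_e
            else:
                delta_f = fitting_uncertainty(curve, reading.nod)
                delta_total = total_uncertainty(delta_e, delta_f)
        except Exception as exc:
            raise PipelineError(f"[uncertainty] film {reading.film_id!r}: {exc}") from exc
        try:
            d_entrance = entrance_dose(df_dose, factors, cf_product)
            d_skin = skin_dose(df_dose, factors.fcal_skin)
        except Exception as exc:
            raise PipelineError(f"[dose_engine] film {reading.film_id!r}: {exc}") from exc

        percent_skin_raw = 100.0 * d_skin / config.prescribed_cGy
        percent_dev_raw = (
            100.0 * abs(d_entrance - config.prescribed_cGy) / config.prescribed_cGy
        )
        logger.info(
            "film %s: NOD=%.4f Df=%.4f cGy Dentrance=%.4f cGy Dskin=%.4f cGy",
            reading.film_id, reading.nod, df_dose, d_entrance, d_skin,
        )
        rows.append(
            {
                "film_id": reading.film_id,
                "encapsulated": reading.encapsulated,
                "od_pre": reading.od_pre,
                "od_post": reading.od_post,
                "nod": reading.nod,
                "df_cGy": df_dose,
                "delta_e_cGy": delta_e,
                "delta_f_cGy": delta_f,
                "delta_total_cGy": delta_total,
                "percent_uncertainty": 100.0 * delta_total / df_dose
                if df_dose > 0
                else float("nan"),
                "fcal_entrance": factors.fcal_entrance,
                "cf_product": cf_product,
                "d_entrance_cGy": d_entrance,
                "fcal_skin": factors.fcal_skin,
                "d_skin_cGy": d_skin,
                "prescribed_cGy": config.prescribed_cGy,
                "percent_skin_raw": percent_skin_raw,
                "percent_skin": round(percent_skin_raw, config.skin_percent_decimals)
                if config.skin_percent_decimals > 0
                else int(round(percent_skin_raw)),
                "percent_deviation_raw": percent_dev_raw,
                "percent_deviation": round(percent_dev_raw, config.deviation_decimals),
            }
        )
    return pd.DataFrame(rows)
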