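"""Synthetic film-reading generator.

Emulates the statistical structure of a Co-60 film-dosimetry study so that
every pipeline stage is testable without measured data:

* a cubic ground-truth OD→dose response (the measured EBT2/Co-60 curve by
  default) inverted to produce net optical densities;
* densitometer readout quantised to 0.01 OD, with additive Gaussian noise on
  the net OD signal before quantisation;
* post-exposure OD growth as a single-exponential saturation that stabilises
  within 24 h (1440 min), slower at higher doses;
* correction-factor landscapes with the field's qualitative trends: an
  unencapsulated surface film over-responds with growing field size and
  gantry angle (electron contamination) and under-responds with growing SSD
  and wedge angle, while an encapsulated film is flat in field size and
  gantry angle;
* chamber readings that follow dose-rate scaling only (inverse-square in SSD,
  wedge transmission).

Film measurements are generated in sets of three films per point, the
repeat structure of a typical film study, and all randomness flows from a
single scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .calibration import (
    EBT2_CO60_CURVE,
    CalibrationCurve,
    CalibrationPoint,
    FilmReading,
    dose_to_od,
    od_to_dose,
    quantize_od,
)
from .correction import (
    REFERENCE_CONDITIONS,
    CorrectionFactorSet,
    CorrectionFactorTable,
    PairedReading,
)
from .dose_engine import CO60_DMAX_CM, DepthDoseTable
from .exceptions import FilmDoseError, InvalidReadingError

# Internal stream labels so each generator draws from an independent,
# reproducible substream of the scenario seed.
_STREAM_CALIBRATION = 1
_STREAM_LANDSCAPE = 2
_STREAM_TREATMENT = 3

#: Default knot grids for the correction-factor landscape (the measured
#: ranges of the study design: field 4-24 cm, SSD 75-120 cm, gantry 0-90 deg,
#: wedge 15-60 deg plus the open-field reference at 0).
DEFAULT_CF_GRIDS: dict[str, tuple[float, ...]] = {
    "field_size_cm": tuple(float(v) for v in range(4, 25, 2)),
    "ssd_cm": tuple(float(v) for v in range(75, 121, 5)),
    "gantry_deg": tuple(float(v) for v in range(0, 91, 10)),
    "wedge_deg": (0.0, 15.0, 30.0, 45.0, 60.0),
}


def _unencapsulated_response(parameter: str, value: float) -> float:
    """Ground-truth normalised response of a bare surface film.

    Linear trends with the qualitative structure of contaminating-electron
    physics: rising with field size and gantry angle, falling with SSD
    (fewer low-energy scattered photons reach the film) and wedge angle
    (beam hardening).  Normalised to 1 at the reference condition.
    """
    ref = REFERENCE_CONDITIONS[parameter]
    slopes = {
        "field_size_cm": 0.009,
        "ssd_cm": -0.0025,
        "gantry_deg": 0.0014,
        "wedge_deg": -0.003,
    }
    return 1.0 + slopes[parameter] * (value - ref)


def _encapsulated_response(parameter: str, value: float) -> float:
    """Normalised response of an encapsulated film: flat in field size and
    gantry angle (the cap absorbs contaminating electrons), mildly falling
    with SSD and wedge angle."""
    ref = REFERENCE_CONDITIONS[parameter]
    slopes = {
        "field_size_cm": 0.0,
        "ssd_cm": -0.0020,
        "gantry_deg": 0.0,
        "wedge_deg": -0.0025,
    }
    return 1.0 + slopes[parameter] * (value - ref)


def _dose_rate_scale(parameter: str, value: float) -> float:
    """Chamber-dose scaling of the machine setting relative to reference.

    Inverse-square in SSD; wedge transmission falls exponentially with wedge
    angle; field size and gantry leave the delivered reference dose unchanged.
    """
    if parameter == "ssd_cm":
        return (REFERENCE_CONDITIONS["ssd_cm"] / value) ** 2
    if parameter == "wedge_deg":
        return float(np.exp(-0.005 * value))
    return 1.0


def default_cf_truth(grids: Mapping[str, Sequence[float]] | None = None) -> CorrectionFactorSet:
    """Ground-truth correction-factor tables (CF = 1 / normalised response)."""
    grids = grids or DEFAULT_CF_GRIDS
    tables = {}
    for parameter, values in grids.items():
        knots = tuple(
            (float(v), 1.0 / _unencapsulated_response(parameter, float(v)))
            for v in sorted(values)
        )
        tables[parameter] = CorrectionFactorTable(
            parameter=parameter,
            knots=knots,
            reference_value=REFERENCE_CONDITIONS[parameter],
        )
    return CorrectionFactorSet(tables=tables)


# ---------------------------------------------------------------------------
# Post-exposure optical-density growth
# ---------------------------------------------------------------------------

#: Growth time constants anchoring the dose→tau interpolation (minutes).
TAU_AT_50_CGY = 120.0
TAU_AT_800_CGY = 400.0

#: Nominal stabilisation time: readings are taken 24 h after exposure.
STABILIZATION_MINUTES = 1440.0


@dataclass(frozen=True)
class GrowthModel:
    """Single-exponential post-exposure darkening model.

    The net OD approaches ``plateau_nod`` as ``1 - exp(-t/tau)``; higher
    doses give both a higher plateau (via the inverse calibration curve) and
    a slower approach (larger ``tau``), so low doses stabilise sooner.
    """

    plateau_nod: float
    tau: float  # minutes
    t_stable: float = STABILIZATION_MINUTES

    def __post_init__(self) -> None:
        if self.plateau_nod <= 0:
            raise InvalidReadingError(f"plateau_nod must be > 0, got {self.plateau_nod}")
        if self.tau <= 0:
            raise InvalidReadingError(f"tau must be > 0, got {self.tau}")

    @classmethod
    def for_dose(
        cls, dose: float, curve: CalibrationCurve = EBT2_CO60_CURVE
    ) -> "GrowthModel":
        """Model for a given absorbed dose: plateau from the inverse curve,
        tau interpolated linearly between the 50 and 800 cGy anchors."""
        if dose <= 0:
            raise InvalidReadingError(f"dose must be > 0, got {dose}")
        plateau = dose_to_od(curve, dose)
        frac = (dose - 50.0) / (800.0 - 50.0)
        tau = TAU_AT_50_CGY + (TAU_AT_800_CGY - TAU_AT_50_CGY) * frac
        tau = float(np.clip(tau, 30.0, 600.0))
        return cls(plateau_nod=plateau, tau=tau)

    def value(self, t: float) -> float:
        """Noise-free net OD at ``t`` minutes after exposure."""
        return self.plateau_nod * (1.0 - float(np.exp(-t / self.tau)))


def generate_growth_series(
    dose: float,
    times: Sequence[float],
    *,
    model: GrowthModel | None = None,
    curve: CalibrationCurve = EBT2_CO60_CURVE,
    noise_sd_od: float = 0.001,
    quantize: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Net-OD readings of one film at the given post-exposure times.

    The underlying saturation curve is strictly non-decreasing; readout noise
    and 0.01-OD quantisation are applied on top.
    """
    times_arr = np.asarray(times, dtype=float)
    if np.any(np.diff(times_arr) < 0):
        raise FilmDoseError("times must be sorted ascending")
    model = model or GrowthModel.for_dose(dose, curve)
    rng = np.random.default_rng(seed)
    series = model.plateau_nod * (1.0 - np.exp(-times_arr / model.tau))
    if noise_sd_od > 0:
        series = series + rng.normal(0.0, noise_sd_od, size=series.shape)
    if quantize:
        series = np.array([quantize_od(v) for v in series])
    return series


def stabilization_time(
    series: Sequence[float],
    times: Sequence[float],
    window: int = 3,
    quantum: float = 0.01,
) -> float | None:
    """First time from which ``window`` consecutive readings change by less
    than one readout quantum; ``None`` if the series never stabilises."""
    s = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if s.shape != t.shape:
        raise FilmDoseError("series and times must have the same length")
    if window < 2 or s.size < window:
        raise FilmDoseError(f"window must be >= 2 and <= series length, got {window}")
    diffs = np.abs(np.diff(s))
    for i in range(s.size - window + 1):
        if np.all(diffs[i : i + window - 1] < quantum - 1e-12):
            return float(t[i])
    return None


# ---------------------------------------------------------------------------
# Measurement scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseScenario:
    """Ground truth and noise model for one simulated measurement campaign.

    ``noise_sd_od`` is the standard deviation of the net-OD signal of a
    single film; ``films_per_point`` mirrors the practice of irradiating
    films in sets of three and averaging; ``commissioning_film_dose`` is the
    film dose (cGy) targeted when measuring calibration/correction factors —
    placed in the upper middle of the calibration range, where the cubic's
    relative sensitivity to OD noise is smallest.
    """

    true_curve: CalibrationCurve = EBT2_CO60_CURVE
    cf_truth: CorrectionFactorSet = field(default_factory=default_cf_truth)
    fcal_entrance: float = 4.134
    noise_sd_od: float = 0.001
    quantize: bool = True
    seed: int = 0
    films_per_point: int = 3
    base_od: float = 0.20
    commissioning_film_dose: float = 400.0

    def __post_init__(self) -> None:
        if self.noise_sd_od < 0:
            raise InvalidReadingError(f"noise_sd_od must be >= 0, got {self.noise_sd_od}")
        if self.films_per_point < 1:
            raise InvalidReadingError("films_per_point must be >= 1")

    def with_seed(self, seed: int) -> "ResponseScenario":
        return replace(self, seed=seed)

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def _noisy_nod(self, nod_true: float, rng: np.random.Generator) -> float:
        nod = nod_true
        if self.noise_sd_od > 0:
            nod += rng.normal(0.0, self.noise_sd_od)
        if self.quantize:
            nod = quantize_od(nod)
        return max(nod, 0.0)


def generate_calibration_dataset(
    scenario: ResponseScenario, doses: Sequence[float]
) -> list[CalibrationPoint]:
    """Calibration points: true NOD from the inverse curve plus readout noise."""
    rng = scenario._rng(_STREAM_CALIBRATION)
    points = []
    for dose in doses:
        nod_true = dose_to_od(scenario.true_curve, dose)
        points.append(CalibrationPoint(nod=scenario._noisy_nod(nod_true, rng), dose=dose))
    return points


def _film_dose_reading(
    scenario: ResponseScenario, true_film_dose: float, rng: np.random.Generator
) -> float:
    """One film's dose reading: true dose -> NOD -> noise -> dose."""
    nod_true = dose_to_od(scenario.true_curve, true_film_dose)
    return od_to_dose(scenario.true_curve, scenario._noisy_nod(nod_true, rng))


def generate_cf_landscape(
    scenario: ResponseScenario,
    grids: Mapping[str, Sequence[float]] | None = None,
) -> dict[str, dict[str, list[PairedReading]]]:
    """Chamber/film pairs along each irradiation parameter, both film
    configurations.

    Returns ``{parameter: {"unencapsulated": [...], "encapsulated": [...]}}``
    with ``films_per_point`` film readings per setting.  The chamber dose
    follows dose-rate scaling only; the unencapsulated film response embeds
    the scenario's ground-truth correction factors (Rf = Ric / (Fcal * CF)).
    """
    grids = grids or {
        p: tuple(v for v, _ in t.knots) for p, t in scenario.cf_truth.tables.items()
    }
    rng = scenario._rng(_STREAM_LANDSCAPE)
    ric_reference = scenario.fcal_entrance * scenario.commissioning_film_dose
    landscape: dict[str, dict[str, list[PairedReading]]] = {}
    for parameter, values in grids.items():
        unenc: list[PairedReading] = []
        enc: list[PairedReading] = []
        for value in sorted(values):
            ric = ric_reference * _dose_rate_scale(parameter, float(value))
            cf_true = scenario.cf_truth.tables[parameter].lookup(float(value))
            rf_true_unenc = ric / (scenario.fcal_entrance * cf_true)
            rf_true_enc = (
                ric / scenario.fcal_entrance
                * _encapsulated_response(parameter, float(value))
            )
            for _ in range(scenario.films_per_point):
                unenc.append(
                    PairedReading(
                        ric=ric,
                        rf=_film_dose_reading(scenario, rf_true_unenc, rng),
                        condition=(parameter, float(value)),
                    )
                )
                enc.append(
                    PairedReading(
                        ric=ric,
                        rf=_film_dose_reading(scenario, rf_true_enc, rng),
                        condition=(parameter, float(value)),
                    )
                )
        landscape[parameter] = {"unencapsulated": unenc, "encapsulated": enc}
    return landscape


def normalized_response(
    readings: Sequence[PairedReading], reference_value: float
) -> list[tuple[float, float]]:
    """(setting, normalised response) pairs: (Rf/Ric) over its reference value.

    Repeated films at a setting are pooled by the mean before normalising.
    """
    pooled: dict[float, list[PairedReading]] = {}
    for r in readings:
        pooled.setdefault(r.condition[1], []).append(r)
    if reference_value not in pooled:
        raise FilmDoseError(f"no reading at reference value {reference_value}")

    def response(rs: list[PairedReading]) -> float:
        return float(np.mean([r.rf for r in rs]) / np.mean([r.ric for r in rs]))

    ref = response(pooled[reference_value])
    return [(v, response(rs) / ref) for v, rs in sorted(pooled.items())]


def estimate_cf_set(
    landscape: Mapping[str, Mapping[str, Sequence[PairedReading]]],
    configuration: str = "unencapsulated",
) -> CorrectionFactorSet:
    """Correction-factor tables estimated from a generated landscape."""
    tables = {
        parameter: CorrectionFactorTable.from_paired_readings(
            parameter, series[configuration]
        )
        for parameter, series in landscape.items()
    }
    return CorrectionFactorSet(tables=tables)


@dataclass(frozen=True)
class SimulatedTreatment:
    """Films for one treatment condition plus the generating ground truth."""

    conditions: Mapping[str, float]
    readings: tuple[FilmReading, ...]
    true_film_dose: float
    true_cf_product: float
    prescribed: float


def simulate_treatment_readings(
    scenario: ResponseScenario,
    conditions: Sequence[Mapping[str, float]],
    prescribed: float = 200.0,
) -> list[SimulatedTreatment]:
    """End-to-end fixture: surface-film readings whose pipeline reconstruction
    should recover the prescribed entrance dose.

    The machine is assumed to deliver the prescription at Dmax under every
    condition (treatment time compensates for dose-rate changes), so the true
    film dose is prescribed / (Fcal_entrance * PiCF(conditions)).
    """
    rng = scenario._rng(_STREAM_TREATMENT)
    out = []
    for i, condition in enumerate(conditions):
        cf_product = scenario.cf_truth.product(condition)  # raises on unknown keys
        df_true = prescribed / (scenario.fcal_entrance * cf_product)
        nod_true = dose_to_od(scenario.true_curve, df_true)
        readings = tuple(
            FilmReading(
                film_id=f"sim-{i:03d}-{j}",
                od_pre=scenario.base_od,
                od_post=scenario.base_od + scenario._noisy_nod(nod_true, rng),
                encapsulated=False,
            )
            for j in range(scenario.films_per_point)
        )
        out.append(
            SimulatedTreatment(
                conditions=dict(condition),
                readings=readings,
                true_film_dose=df_true,
                true_cf_product=cf_product,
                prescribed=prescribed,
            )
        )
    return out


def sweep_conditions(
    n: int, seed: int = 0, grids: Mapping[str, Sequence[float]] | None = None
) -> list[dict[str, float]]:
    """Sample ``n`` mixed condition sets spanning the measured parameter
    ranges (uniformly within each table's knot range, one to all four
    parameters off reference per condition)."""
    grids = grids or DEFAULT_CF_GRIDS
    rng = np.random.default_rng([seed, 17])
    parameters = list(grids)
    out = []
    for _ in range(n):
        k = int(rng.integers(1, len(parameters) + 1))
        chosen = rng.choice(len(parameters), size=k, replace=False)
        condition = {}
        for idx in chosen:
            p = parameters[int(idx)]
            lo, hi = min(grids[p]), max(grids[p])
            condition[p] = float(np.round(rng.uniform(lo, hi), 1))
        out.append(condition)
    return out


def generate_pdd_table(
    dmax_depth: float = CO60_DMAX_CM,
    max_depth: float = 20.0,
    step: float = 0.5,
    mu_per_cm: float = 0.06,
    surface_pdd: float = 30.0,
) -> DepthDoseTable:
    """Synthetic Co-60-like percentage-depth-dose table.

    Exponential attenuation beyond Dmax with a linear build-up from the
    surface; a stand-in shape for demonstrations and tests, not clinical
    beam data.
    """
    knots: list[tuple[float, float]] = [(0.0, surface_pdd)]
    depth = dmax_depth
    while depth <= max_depth + 1e-9:
        knots.append((round(depth, 4), 100.0 * float(np.exp(-mu_per_cm * (depth - dmax_depth)))))
        depth += step
    return DepthDoseTable(knots=tuple(knots), dmax_depth=dmax_depth)
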