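# Methods

## The measurement model

A radiochromic film placed on the skin at the beam entrance polymerises under
irradiation and darkens; a point densitometer reports optical density (OD) on
a 2-decimal display.  The dose signal is the net optical density
`NOD = OD_post − OD_pre`, and absorbed dose follows from a cubic calibration

    D(OD) = a·OD³ + b·OD² + c·OD + d        [cGy]

fitted against ionisation-chamber doses measured under the same conditions.
All doses in the package are centigray.  The transcribed Co-60/EBT2 curve
shipped as `EBT2_CO60_CURVE` is (a, b, c, d) = (1685, −187.9, 1006, −2.328)
on the OD domain [0, 0.65], which covers the 50–800 cGy calibration span.

The curve must be strictly increasing to be invertible; this is enforced at
construction on a 1000-point grid with zero tolerance on the sign of the
increments.  Inversion is by bisection to |ΔD| < 1e-9 cGy.  Negative NODs and
negative raw doses are physically suspicious but not silently repaired: they
raise a warning, and clamping to zero happens only at report generation when
explicitly requested.

### Fitting

`fit_calibration` is ordinary least squares on the Vandermonde design
[OD³, OD², OD, 1] (≥5 points, ≥4 distinct NODs).  Coefficient standard
deviations come from the standard OLS covariance σ²(XᵀX)⁻¹ with
σ² = RSS/(n−4); `r_fit` is the Pearson correlation between measured and
fitted doses.  A noiseless monotone cubic is recovered to better than 1e-6
relative — this closure is a test invariant.

## Uncertainty budget

Two sources are propagated to first order:

* experimental: `δe = |D′(OD)|·δOD`, with δOD defaulting to one display
  quantum (0.01 OD) used as a standard deviation;
* fitting: `δf = √(δa²OD⁶ + δb²OD⁴ + δc²OD² + δd²)` from the coefficient SDs;

combined in quadrature.  Because the curve's slope is ≈1000 cGy/OD, δOD = 0.01
alone contributes ≈10 cGy at any dose — the budget is therefore dominated by
the readout term at low film doses, and percentage uncertainty *decreases*
with film dose while absolute uncertainty grows.  The budget machinery is
verified through its closed forms (quadrature symmetry, homogeneity in δOD,
monotone growth along the calibration range) rather than against any single
published percentage band, which would require the original fit's coefficient
SDs.

## Correction factors

Contaminating electrons from the collimator head and air inflate a bare
surface film's response; their yield varies with field size, SSD, gantry
angle and wedge angle.  Each parameter is corrected independently
(parameters are varied one at a time, so the factors are treated as
separable):

    CF(p) = (Ric/Rf)_clinical / (Ric/Rf)_reference

with repeated films pooled by the mean before the ratio.  Tables are
normalised to CF = 1 at the reference setting (10 cm × 10 cm open field,
SSD 100 cm, gantry 0°, no wedge; "no wedge" is modelled as wedge angle 0).
Between measured knots CF is interpolated piecewise-linearly — the minimal
assumption given no information about between-knot behaviour — and lookups
outside the measured range raise rather than extrapolate.

Film-configuration comparisons (unencapsulated vs encapsulated response
across matched settings) use a paired two-sided t-test at α = 0.05; the test
choice is recorded in the result metadata.  Identical series are reported as
p = 1 with zero difference instead of the undefined zero-variance statistic.

## Entrance and skin dose

The entrance dose lives at the depth of maximum dose (0.5 cm for Co-60); a
surface film reads only the build-up-depleted surface dose, hence the
entrance calibration factor `Fcal,entrance = Ric/Rf` at reference conditions
(≈4.134 for a bare film: the surface film reads ≈24% of the Dmax dose) and

    D_entrance = Df · Fcal,entrance · ΠCF.

Dose at depth d is `D_entrance · PDD(d)/100`, with PDD linearly interpolated
and pinned to 100% at Dmax.

The skin dose is referenced to 0.070 mm (the radiosensitive basal layer),
slightly shallower than the film's active layer (0.080 mm for a single film;
0.935 mm for the bottom film of a four-film stack).  The OD at 0.070 mm is
obtained by linear extrapolation in depth through the two active-layer
measurements, and

    Fcal,skin = D(OD at 0.070 mm) / D(OD at 0.080 mm).

By default both ODs are first quantised to the 2-decimal display, mirroring
how the factor is read off the instrument; the displayed ODs coincide and the
factor is exactly 1.00.  An option computes it from the raw extrapolated ODs
instead (≈0.979 with the shipped curve).  Skin-dose percentages are reported
rounded to the nearest integer with the raw value retained alongside.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, with
ground truth attached so recovery is checkable end to end.

* **Dose response**: NOD = curve⁻¹(true film dose) + Gaussian noise on the
  net signal (`noise_sd_od`, default 0.001 OD), then optional quantisation to
  0.01 OD, applied last.  The noise knob is defined at the net-signal level;
  the pre-irradiation baseline is a fixed 0.20 OD.
* **Post-exposure growth**: single-exponential saturation
  `plateau·(1 − e^(−t/τ))` — the simplest shape with the observed qualitative
  behaviour.  The plateau is the inverse-calibration NOD of the delivered
  dose; τ rises linearly from 120 min at 50 cGy to 400 min at 800 cGy so low
  doses stabilise sooner and every series stabilises (readings change by less
  than one display quantum) well before the 1440-min reading time.
  Stabilisation detection is windowed (default 3 consecutive readings) to be
  robust to quantisation flicker near a display boundary.
* **Correction-factor landscape**: the unencapsulated film's normalised
  response rises linearly with field size (+0.9%/cm) and gantry angle
  (+0.14%/deg) — the contaminating-electron surrogate — and falls with SSD
  (−0.25%/cm) and wedge angle (−0.30%/deg); ground-truth CF is its
  reciprocal.  The encapsulated film is exactly flat in field size and gantry
  angle and mildly falling in SSD and wedge.  Chamber doses follow dose-rate
  scaling only: inverse-square in SSD about 100 cm and an exponential wedge
  transmission; field size and gantry leave the delivered reference dose
  unchanged.  Slope magnitudes are chosen to sit in the middle of the ranges
  reported for surface detectors on megavoltage beams.
* **Repeat structure**: films are generated in sets of three per measurement
  point and pooled by the mean — the standard practice of irradiating film
  sets.  Factor commissioning (CF tables, Fcal) targets a film dose of
  400 cGy, in the upper middle of the calibration range: the cubic's
  *relative* sensitivity to OD noise there (≈0.4%/0.001 OD) is about five
  times smaller than at the ≈48 cGy surface-film dose (≈2%/0.001 OD), which
  is where a physicist would calibrate ratio quantities that are themselves
  dose-level independent.
* **Treatment simulation**: the machine is assumed to deliver the
  prescription at Dmax under every condition (treatment time compensates for
  dose-rate changes), so the true surface-film dose is
  `prescribed / (Fcal,entrance · ΠCF)` and pipeline reconstruction should
  return the prescription exactly in the noiseless limit (a test invariant).
* **Determinism**: one integer seed per scenario; each generator draws from
  an independent substream (`default_rng([seed, stream])`), so identical
  seeds give byte-identical datasets regardless of call order.

What the generator does **not** model: physically accurate electron
contamination spectra, 2-D film scans and lateral scanner response,
film-orientation effects, inter-batch film variation, or patient-related
variability.  Passing recovery tests therefore demonstrates that the analysis
chain is self-consistent under the assumed noise structure, not that a
clinical measurement will reach the same accuracy.

## Problem sizes and numerical choices

The default verification workloads are deliberately small: 10-point
calibration refits, 36-knot CF landscapes with 3 films per knot, and a
20-condition entrance-dose sweep (3 films per condition, σ_OD = 0.001,
quantisation off) spanning field 4–24 cm, SSD 75–120 cm, gantry 0–90°,
wedge 0–60°.  At these settings the maximum entrance-dose deviation is
dominated by the surface-film readout term (≈1.2% SD per 3-film mean), and
the sweep maximum lands at 1.5–3%, consistent with an in-phantom accuracy
claim of "within 3%".

Other fixed choices: bisection tolerance 1e-9 cGy; monotonicity grid 1000
points, strict sign; CF knot lookups exact at knots; report rounding integer
for skin percentages and 2 decimals for deviations (raw values always
emitted); all depths in cm except film-layer depths in mm, with units in
column names.

## Known limitations

Exit-side doses, peripheral/off-axis doses, multi-channel (RGB) scanner
dosimetry and chamber-side reference dosimetry are out of scope; chamber
doses enter as given inputs.  The shipped cubic is specific to one
film batch, densitometer and beam — a different readout device requires
refitting.  The PDD table produced by `generate_pdd_table` is a synthetic
exponential stand-in for demonstrations, not clinical beam data.
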