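"""Exception and warning types shared across the package."""


class FilmDoseError(Exception):
    """Base class for all filmdose errors."""


class InvalidReadingError(FilmDoseError):
    """A densitometer reading violates its physical constraints."""


class FitError(FilmDoseError):
    """Calibration fit cannot be performed (too few points, rank deficiency)."""


class MonotonicityError(FilmDoseError):
    """A fitted calibration polynomial is not strictly increasing on its domain."""


class DomainError(FilmDoseError):
    """An optical density lies outside a curve's valid domain (strict mode)."""


class OutOfRangeError(FilmDoseError):
    """A value lies outside the attainable/tabulated range (dose, depth, knot)."""


class ExtrapolationError(OutOfRangeError):
    """A correction-factor lookup outside the measured knot range."""


class ConfigurationError(FilmDoseError):
    """Required configuration (e.g. coefficient standard deviations) is missing."""


class InsufficientDataError(FilmDoseError):
    """Not enough observations for a statistical comparison."""


class SchemaError(FilmDoseError):
    """A CSV file is missing a required column."""


class ParseError(FilmDoseError):
    """A CSV cell could not be parsed as the expected type."""


class PipelineError(FilmDoseError):
    """A pipeline stage failed; the message names the stage."""


class DosimetryWarning(UserWarning):
    """Non-fatal dosimetry conditions (negative net OD, clamped dose, ...)."""
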