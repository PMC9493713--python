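"""Exception hierarchy for the osteokin pipeline."""


class OsteokinError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(OsteokinError):
    """Invalid configuration (filter cutoffs, window sizes, profile timings...)."""


class FormatError(OsteokinError):
    """Malformed input file (ragged rows, non-triple headers...)."""


class DegenerateFitError(OsteokinError):
    """Rigid fit is ill-posed: fewer than 3 points, or collinear points."""


class UnusableBodyError(OsteokinError):
    """A rigid body never has the minimum number of visible markers."""


class DegenerateMuscleError(OsteokinError):
    """Muscle with zero reference length."""


class NoStrikeError(OsteokinError):
    """Event detection found no excursion above threshold."""
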