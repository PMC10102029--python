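"""Exception hierarchy: validation errors (bad inputs/config) vs data errors
(well-formed files whose contents violate physical constraints) vs numerical
failures. The CLI maps these onto exit codes 2 and 3."""


class IlrkitError(Exception):
    """Base class for all ilrkit errors."""


class ValidationError(IlrkitError, ValueError):
    """Invalid parameter, configuration, or domain-object state."""


class DataError(IlrkitError, ValueError):
    """Physically inconsistent measurement data (e.g. titrant volume dips)."""


class CoverageError(DataError):
    """A blank record does not span the sample's time range."""


class NumericalError(IlrkitError, RuntimeError):
    """A numerical routine failed to produce a usable result."""
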