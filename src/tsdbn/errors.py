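"""Exception hierarchy shared across the package."""


class TsdbnError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TsdbnError):
    """An input table is missing a required column or has a bad layout."""


class ParseError(TsdbnError):
    """A cell could not be parsed (e.g. negative or non-numeric count)."""


class DegenerateSampleError(TsdbnError):
    """A sample with zero total counts cannot be converted to proportions."""


class StructureError(TsdbnError):
    """A network structure violates the conditional-Gaussian restrictions."""


class IncompleteEvidenceError(TsdbnError):
    """A density or prediction was requested with a parent value missing."""


class InsufficientDataError(TsdbnError):
    """Too few observations to run the requested statistical comparison."""
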