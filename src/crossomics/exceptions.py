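"""Exception hierarchy used across the pipeline."""


class CrossOmicsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CrossOmicsError):
    """Invalid simulation or pipeline configuration."""


class AlignmentError(CrossOmicsError):
    """Sample or feature identifiers of two inputs do not line up."""


class DomainError(CrossOmicsError):
    """Values outside the domain required by an operation (e.g. non-positive
    concentrations before a log transform)."""


class UndefinedRatioError(CrossOmicsError):
    """Wald ratio requested with a zero exposure effect."""
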