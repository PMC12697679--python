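"""Exception hierarchy shared across the package."""


class RacoonError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RacoonError):
    """A file or table does not conform to the expected layout."""


class DataError(RacoonError):
    """Input values violate a precondition (bad labels, empty classes, ...)."""


class ParameterError(RacoonError):
    """A configuration value is out of its admissible range."""
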