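"""Exception hierarchy for the microwear toolkit."""


class MicrowearError(Exception):
    """Base class for all package errors."""


class FormatError(MicrowearError):
    """A file does not conform to the expected on-disk format."""


class SchemaError(MicrowearError):
    """A measurement table carries unknown or missing columns."""


class ConfigurationError(MicrowearError):
    """Settings violate their invariants (e.g. material-ratio p >= q)."""


class ComputationError(MicrowearError):
    """A numerical operation cannot proceed (degenerate geometry, rank deficiency)."""


class DesignError(MicrowearError):
    """A statistical comparison is ill-posed (missing factor levels, empty subset)."""


class SampleSizeError(MicrowearError):
    """Too few observations remain after trimming for a robust statistic."""
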