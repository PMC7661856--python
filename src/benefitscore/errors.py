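"""Exception hierarchy.

Configuration problems (bad column maps, bad config ranges) are kept
distinct from data problems (unparseable rows, degenerate inputs) so the
CLI can map them to distinct exit codes.
"""


class BenefitScoreError(Exception):
    """Base class for package errors."""


class ConfigurationError(BenefitScoreError):
    """Invalid configuration: missing columns, bad ranges, bad paths."""


class DataError(BenefitScoreError):
    """Malformed or degenerate input data."""


class RuleInapplicableError(DataError):
    """A clonality rule was asked for evidence the annotation lacks."""


class DegenerateInputError(DataError):
    """Statistically degenerate input (no events, constant marker, ...)."""
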