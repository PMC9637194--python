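"""Exception hierarchy shared across the package."""


class EpirelapseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EpirelapseError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(EpirelapseError):
    """A malformed on-disk record; the message carries the line number."""


class ValidationError(EpirelapseError):
    """Cross-record consistency failure (dangling references, bad pairings)."""


class EmptyComparisonError(EpirelapseError):
    """A two-sample comparison with zero shared, covered sites."""


class EmptySelectionError(EpirelapseError):
    """A summary or selection over an empty site/gene set."""
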