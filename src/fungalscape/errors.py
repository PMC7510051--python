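"""Exception hierarchy shared across the pipeline."""


class FungalscapeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FungalscapeError, ValueError):
    """A file or table violates the expected format (negative counts,
    duplicate IDs, missing columns, malformed trees)."""


class ConfigurationError(FungalscapeError, ValueError):
    """An invalid parameter combination (out-of-range fractions,
    impossible thresholds)."""


class QCError(FungalscapeError, ValueError):
    """Quality control cannot proceed (zero-total samples, nothing
    survives the filter chain)."""
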