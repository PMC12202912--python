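"""Exception hierarchy for ocudelay."""


class OcudelayError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OcudelayError, ValueError):
    """A parameter document or parameter set is invalid.

    The message enumerates every problem found rather than stopping at
    the first one.
    """


class IndexLookupError(OcudelayError, LookupError):
    """A (country, year) entry is absent from a price-index table.

    Missing entries are never interpolated; the caller must supply them.
    """


class UnknownDiagnosisError(OcudelayError, LookupError):
    """A cohort record names a diagnosis with no matching profile."""
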