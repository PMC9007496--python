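"""Exception types shared across the package."""


class KymotraceError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(KymotraceError, ValueError):
    """A simulation or experiment configuration violates its invariants."""


class RangeError(KymotraceError, ValueError):
    """A window, interval or path falls outside the data it indexes."""


class SampleSizeError(KymotraceError, ValueError):
    """A statistical routine received fewer values than it requires."""


class InvalidTraceError(KymotraceError, ValueError):
    """A fluorescence trace cannot support the requested computation."""


class NormalizationError(KymotraceError, ValueError):
    """Control-group normalization is undefined (zero control mean)."""
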