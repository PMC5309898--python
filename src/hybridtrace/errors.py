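"""Exception types shared across the package."""


class HybridtraceError(Exception):
    """Base class for package errors."""


class ConfigurationError(HybridtraceError):
    """Invalid configuration: unknown samples, groups, roles or parameters."""


class VCFParseError(HybridtraceError):
    """Malformed VCF input."""


class UndefinedStatisticError(HybridtraceError):
    """A statistic's denominator is zero or no informative sites remain."""
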