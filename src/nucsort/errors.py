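"""Exception types shared across the package."""


class NucsortError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NucsortError, ValueError):
    """An invalid or infeasible parameter/configuration value."""


class SamParseError(NucsortError, ValueError):
    """A malformed SAM record; message names the offending record/line."""
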