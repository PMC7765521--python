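"""Exception taxonomy shared across the pipeline.

The CLI maps these onto distinct exit codes so batch callers can tell a bad
configuration from a malformed recording file.
"""


class SozlocError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SozlocError):
    """Inconsistent or invalid parameters (bad split plan, band above Nyquist,

    SOZ label naming a channel that does not exist, ...)."""


class FormatError(SozlocError):
    """Malformed or empty input data (channel length mismatch, zero channels,

    recording shorter than one segment, ...)."""


class BalancingError(SozlocError):
    """Class-balancing cannot proceed (fewer than two minority rows)."""
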