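"""Exception hierarchy for fmtlink."""


class FmtlinkError(Exception):
    """Base class for all fmtlink errors."""


class FormatError(FmtlinkError):
    """A file does not conform to the expected on-disk format."""


class IntegrityError(FmtlinkError):
    """Input parses but violates a cross-record invariant."""


class ConfigError(FmtlinkError):
    """Invalid configuration value or reference to an unknown entity."""


class NotEstimableError(FmtlinkError):
    """A statistic cannot be computed from the data provided."""
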