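"""Exception hierarchy shared across the package."""


class TsnscanError(Exception):
    """Base class for all package errors."""


class VcfParseError(TsnscanError):
    """Raised when a VCF record cannot be parsed; message names the offending line."""


class PanelError(TsnscanError):
    """Raised for malformed sample→population panels (duplicates, empty files)."""


class GeneModelError(TsnscanError):
    """Raised for malformed gene model (BED) input."""


class ConfigError(TsnscanError):
    """Raised for invalid or out-of-range run configuration."""


class PipelineError(TsnscanError):
    """Raised when a scan stage fails; message names the stage."""
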