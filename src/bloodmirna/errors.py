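"""Exception hierarchy used across the pipeline."""


class BloodMirnaError(Exception):
    """Base class for all package errors."""


class FormatError(BloodMirnaError):
    """A file does not follow the documented on-disk dialect."""


class ContentError(BloodMirnaError):
    """Well-formed input whose content violates a documented invariant."""


class ConfigError(BloodMirnaError):
    """A configuration value is outside its valid domain."""


class EstimationError(BloodMirnaError):
    """A statistical estimation step cannot proceed on the given data."""
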