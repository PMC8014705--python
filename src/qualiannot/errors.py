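"""Exception hierarchy shared across the package."""


class QualiAnnotError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(QualiAnnotError):
    """Invalid session or dropdown configuration (empty/duplicate keywords, bad fractions...)."""


class ValidationError(QualiAnnotError):
    """A record or table row violates the schema derived from the session configuration."""


class UnsupportedOperationError(QualiAnnotError):
    """Operation not defined for the session's modality."""


class UnmappedSlotError(QualiAnnotError):
    """A keyboard-shortcut slot beyond the configured keyword count."""


class SchemaError(QualiAnnotError):
    """CSV header does not match the schema implied by the declared configuration."""


class RoiFormatError(QualiAnnotError):
    """Byte stream is not a valid ImageJ ROI file."""


class UnsupportedRoiTypeError(QualiAnnotError):
    """ROI type code outside the supported subset."""


class EmptyMaskError(QualiAnnotError):
    """ROI rasterization produced no pixels inside the image."""
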