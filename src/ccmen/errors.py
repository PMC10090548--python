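"""Exception hierarchy shared across the package."""


class CcmenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CcmenError):
    """An input file is missing required columns or has the wrong layout."""


class StructureError(CcmenError):
    """Table contents violate a structural constraint (counts, codes, ranges)."""


class DegenerateModelError(CcmenError):
    """Model inputs carry no binding mass at all (every CBE is zero)."""


class FitError(CcmenError):
    """A calibration fit cannot be performed on the supplied points."""


class ConfigError(CcmenError):
    """A run configuration is inconsistent or incomplete."""
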