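"""Exception hierarchy for sgafit.

All package-raised errors derive from :class:`SgafitError` so callers can
catch pipeline failures without trapping programming errors.
"""


class SgafitError(Exception):
    """Base class for all sgafit errors."""


class ScreenFormatError(SgafitError, ValueError):
    """A file on disk violates its documented format (reported with line numbers)."""


class ConfigError(SgafitError, ValueError):
    """Invalid, unknown or missing configuration keys; message lists all problems."""


class CapacityError(SgafitError, ValueError):
    """Library does not fit the requested plate format."""


class UnknownLocusError(SgafitError, KeyError):
    """A query locus is absent from the genome map."""


class ProcessingError(SgafitError, RuntimeError):
    """A pipeline stage cannot proceed (e.g. a plate with too few colonies)."""


class StructuralError(SgafitError, ValueError):
    """Inputs that must describe the same universe (genes, layout) disagree."""
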