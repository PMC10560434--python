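"""Exception types shared across the package."""


class EstuarchError(Exception):
    """Base class for package-specific errors."""


class FormatError(EstuarchError):
    """A file violates the expected TSV dialect (ragged rows, duplicate
    identifiers, negative counts, ...)."""


class EmptyResultError(EstuarchError):
    """An operation removed every sample/feature or has nothing to sum."""


class DegenerateFitError(EstuarchError):
    """Model fitting is impossible (e.g. no variance in the response)."""


class DesignError(EstuarchError):
    """A statistical design is aliased/confounded (zero residual df)."""


class UndefinedCorrelationError(EstuarchError):
    """A correlation is requested on a constant (zero-variance) vector."""
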