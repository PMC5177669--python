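"""Exception hierarchy for the abcline package.

All package-raised errors derive from :class:`AbclineError` so callers can
catch everything from one base while the CLI maps each subtype to a
stage-named message.
"""


class AbclineError(Exception):
    """Base class for all abcline errors."""


class ParameterError(AbclineError, ValueError):
    """A user-supplied parameter is out of its documented range."""


class GenerationError(AbclineError, RuntimeError):
    """Synthetic-anatomy sampling failed (e.g. point outside the skull
    after the retry budget); the message names the offending parameter."""


class GeometryError(AbclineError, RuntimeError):
    """A geometric query is ill-posed (no ray exit, degenerate mesh)."""


class UndefinedDirectionError(GeometryError):
    """Ray direction undefined because the two defining points coincide."""


class ExtractionError(AbclineError, RuntimeError):
    """Isosurface extraction failed (e.g. empty occupancy volume)."""


class SchemaError(AbclineError, ValueError):
    """A record or landmark set is missing a required field; the message
    names the missing field."""


class UndefinedCorrelationError(AbclineError, ValueError):
    """Pearson correlation undefined (zero-variance column); the message
    names the column."""


class PackagingError(AbclineError, RuntimeError):
    """A packaged fixture failed its integrity check."""
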