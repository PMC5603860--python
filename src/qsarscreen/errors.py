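"""Exception hierarchy for the pipeline.

All user-facing failures derive from :class:`QsarError` so callers can
catch one base class at pipeline boundaries (CLI, batch scripts).
"""


class QsarError(Exception):
    """Base class for all package errors."""


class ConfigurationError(QsarError):
    """Invalid user-supplied configuration (bad spec bounds, unknown names)."""


class ProcessingError(QsarError):
    """A data-reduction step produced an unusable result (e.g. empty table)."""


class ModelingError(QsarError):
    """Model fitting failed (rank deficiency, degenerate leave-one-out)."""


class ValidationError(QsarError):
    """Validation statistics cannot be computed (e.g. zero-variance input)."""
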