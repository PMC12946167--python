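"""Typed exceptions raised across the pipeline.

Every validation failure raises one of these; counts are never silently
coerced and malformed inputs are never passed through.
"""


class ImmunotransitError(Exception):
    """Base class for all package errors."""


class FormatError(ImmunotransitError):
    """A file on disk does not conform to its expected dialect."""


class ValidationError(ImmunotransitError):
    """An in-memory object violates a data-model invariant."""


class ConfigError(ImmunotransitError):
    """A simulation or pipeline configuration is inconsistent."""


class AnalysisError(ImmunotransitError):
    """An analysis precondition is not met (too few samples, no overlap, ...)."""
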