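"""Exception hierarchy shared across the pipeline stages."""


class MeshopsError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MeshopsError):
    """A file could not be parsed; the message names the offending line."""


class IntegrityError(MeshopsError):
    """Input data violates a uniqueness or consistency constraint."""


class ConfigurationError(MeshopsError):
    """An operation was invoked with an inconsistent configuration."""


class ProfileError(MeshopsError):
    """A profile cannot be built (e.g. empty bibliography)."""


class CorrectionError(MeshopsError):
    """The empirical-significance correction cannot be computed."""


class LabelingError(MeshopsError):
    """A label set cannot be constructed from the given inputs."""


class EvaluationError(MeshopsError):
    """ROC evaluation is undefined for the given labels or scores."""
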