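"""Exception types shared across the package."""


class SossError(Exception):
    """Base class for all package errors."""


class ValidationError(SossError, ValueError):
    """An input violates a documented precondition or invariant."""


class IntegrityError(SossError):
    """Persisted artifacts disagree with their manifest."""


class AnnotationParseError(SossError):
    """An annotation file could not be parsed in the requested dialect."""
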