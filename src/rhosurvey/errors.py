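"""Exception types shared across the pipeline."""


class RhosurveyError(Exception):
    """Base class for all package errors."""


class FormatError(RhosurveyError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(RhosurveyError):
    """Parsed data violates a domain invariant."""


class EmptyPositiveSetError(RhosurveyError):
    """A classification was requested against an empty reference set."""


class DegenerateMatrixError(RhosurveyError):
    """A distance matrix carries no information (all-zero distances)."""
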