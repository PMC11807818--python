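"""Exception hierarchy used across the package."""


class DiisurvError(Exception):
    """Base class for all package errors."""


class InvalidReferenceError(DiisurvError):
    """A reference table violates its invariants (e.g. non-positive SD)."""


class MissingDataError(DiisurvError):
    """A required parameter or column is absent from the input."""


class InvalidInputError(DiisurvError):
    """Input values violate a precondition (non-finite, wrong range, duplicates)."""


class InvalidConfigurationError(DiisurvError):
    """A configuration object is internally inconsistent."""


class NoEventsError(DiisurvError):
    """A survival fit was requested on data containing no qualifying events."""


class InsufficientEventsError(DiisurvError):
    """Too few events for the requested diagnostic."""


class InsufficientDataError(DiisurvError):
    """Too few observations for the requested statistic."""


class NonIdentifiableError(DiisurvError):
    """A model term is constant or collinear and cannot be estimated."""


class FittingError(DiisurvError):
    """An iterative fit failed to converge."""
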