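"""Exception types raised by the analysis modules.

All inherit from :class:`ObmixError` so callers can catch the package's
errors with one clause; most also inherit from ``ValueError`` because they
signal invalid inputs.
"""


class ObmixError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ObmixError, ValueError):
    """An argument is outside its documented domain (non-finite, negative SD, ...)."""


class DegenerateBaselineError(ObmixError, ValueError):
    """Baseline fluorescence is non-positive, so ΔF/F is undefined for that ROI."""


class ShapeMismatchError(ObmixError, ValueError):
    """Trials disagree in ROI count or frame count where agreement is required."""


class UnsupportedStimulusError(ObmixError, ValueError):
    """A stimulus specification the pipeline does not handle (e.g. >2 components)."""


class InsufficientTrialsError(ObmixError, ValueError):
    """A required stimulus type has no (or too few) trials in the session."""


class EmptyFieldError(ObmixError, ValueError):
    """Every ROI of a field was excluded, so a per-field summary is undefined."""


class NoReferenceGlomeruliError(ObmixError, ValueError):
    """No glomerulus passed the target-responsiveness threshold."""


class UndefinedIndexError(ObmixError, ValueError):
    """A summary index is undefined for the given class composition."""


class InvalidTrainingSetError(ObmixError, ValueError):
    """Decoder training data contains a single class."""


class InvalidDesignError(ObmixError, ValueError):
    """The session lacks the trial types a decoding design requires."""


class InsufficientReplicatesError(ObmixError, ValueError):
    """Too few fields of view (or samples) for a population-level test."""


class FitFailureError(ObmixError, RuntimeError):
    """A model fit did not converge; the message carries diagnostics."""


class SessionIOError(ObmixError, ValueError):
    """A session directory is inconsistent (manifest/array mismatch, missing metadata)."""
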