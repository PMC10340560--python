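"""Exception hierarchy for the eegfocus pipeline."""


class EEGFocusError(Exception):
    """Base class for all package errors."""


class MontageError(EEGFocusError):
    """A required bipolar derivation is missing or unresolvable."""


class ValidationError(EEGFocusError):
    """Input data violates a structural invariant (shapes, intervals, labels)."""


class ConfigurationError(EEGFocusError):
    """A configuration value is inconsistent with the data or with itself."""


class DegenerateInputError(EEGFocusError):
    """An input is numerically degenerate (e.g. zero-energy denominator)."""


class LateralizationError(EEGFocusError):
    """Lateralization cannot be computed (e.g. no ictal epochs detected)."""


class BalancingError(EEGFocusError):
    """Class balancing is impossible (a class is absent)."""
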