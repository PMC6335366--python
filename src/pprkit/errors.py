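"""Exception hierarchy shared across the toolkit."""


class PprKitError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(PprKitError):
    """A domain object violates one of its invariants."""


class EmptyInputError(PprKitError):
    """An operation received no usable records or rows."""


class DuplicateIdError(ValidationError):
    """Two records in one collection share an identifier."""


class AlphabetError(ValidationError):
    """A sequence contains characters outside the 20-letter amino-acid alphabet."""


class SequenceTooShortError(PprKitError):
    """A sequence is shorter than an encoder's minimum usable length."""


class DegenerateIndexError(ValidationError):
    """An amino-acid property index has zero variance and cannot be standardized."""


class AlignmentError(PprKitError):
    """Feature sets being fused do not cover the same instances in the same order."""


class UndefinedMetricError(PprKitError):
    """A metric (correlation, AUC, F-measure) is undefined for the given input."""


class ConfigError(PprKitError):
    """A configuration object describes an infeasible or inconsistent setup."""
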