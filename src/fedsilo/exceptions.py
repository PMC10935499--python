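"""Exception hierarchy shared across the pipeline."""


class FedsiloError(Exception):
    """Base class for all package errors."""


class ValidationError(FedsiloError, ValueError):
    """A specification or input failed its declared invariants."""


class CohortParseError(ValidationError):
    """A cohort file violated the on-disk dialect; carries row/column context."""


class FeasibilityError(FedsiloError):
    """A client shard configuration cannot satisfy the one-of-each-class rule."""


class ArchitectureError(FedsiloError, ValueError):
    """Model parameters do not match the expected tensor names/shapes."""


class LeakageError(FedsiloError):
    """Test or holdout rows were presented to a fitting routine."""


class UnsupportedOperationError(FedsiloError):
    """Operation not defined for this learner kind (e.g. proximal forests)."""
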