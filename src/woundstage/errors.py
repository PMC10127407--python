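"""Exception hierarchy shared by all modules."""


class WoundStageError(Exception):
    """Base class for package errors."""


class SchemaError(WoundStageError):
    """Malformed table header or column layout."""


class ParseError(WoundStageError):
    """A cell or row could not be parsed into a valid value."""


class BaselineError(WoundStageError):
    """No unwounded (t = 0) reference sample is available."""


class PositivityError(WoundStageError):
    """Intensities must be strictly positive on the linear scale."""


class ConfigurationError(WoundStageError):
    """Inconsistent or incomplete configuration."""


class MembershipError(WoundStageError):
    """A requested gene is absent from the dataset it is required in."""


class ClusterUnrepresentedError(WoundStageError):
    """A temporal cluster has no measured gene in the given dataset."""


class DomainError(WoundStageError):
    """Argument outside its mathematical domain (e.g. negative time)."""


class ValidationError(WoundStageError):
    """Invalid specification of a synthetic cohort or experiment."""
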