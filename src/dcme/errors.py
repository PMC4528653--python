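"""Exception hierarchy for the dcme package."""


class DcmeError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DcmeError, ValueError):
    """A rate, shape or other model parameter is outside its domain."""


class InvalidStateError(DcmeError, ValueError):
    """A state vector has a negative component."""


class StateUnderflowError(DcmeError, ValueError):
    """An update drove a copy number negative (signals a scheduling bug)."""


class ModelSpecError(DcmeError, ValueError):
    """A model configuration file failed schema validation."""


class UsageError(DcmeError, ValueError):
    """An operation was called on a system it does not apply to."""


class GridError(DcmeError, ValueError):
    """A tabulated density was supplied on a non-uniform grid."""


class QueryError(DcmeError, ValueError):
    """A trajectory or ensemble was queried outside its simulated horizon."""


class AccuracyError(DcmeError, ArithmeticError):
    """A numerical routine could not reach its requested tolerance."""
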