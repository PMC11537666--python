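"""Exception hierarchy shared across the package."""


class MRError(Exception):
    """Base class for all mrmediate errors."""


class ConfigurationError(MRError):
    """A config file, column map or parameter set cannot be resolved."""


class DataError(MRError):
    """Input data violates a structural requirement (duplicates, missing fields)."""


class DomainError(MRError):
    """A numeric argument is outside the mathematical domain of an operation."""


class InsufficientInstrumentsError(MRError):
    """Fewer instruments than the estimator requires."""


class PipelineError(MRError):
    """A multi-stage analysis could not complete; the message names the stage."""
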