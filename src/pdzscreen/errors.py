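"""Exception hierarchy shared across the pipeline."""


class PdzScreenError(Exception):
    """Base class for all pdzscreen errors."""


class ConfigurationError(PdzScreenError):
    """A simulation or pipeline configuration field is invalid."""


class FormatError(PdzScreenError):
    """An input file does not conform to its expected format."""


class IntegrityError(PdzScreenError):
    """Input data violates a structural invariant (duplicates, cycles...)."""


class ProcessingError(PdzScreenError):
    """A computation cannot proceed on the given data (too few spots...)."""


class ValidationError(PdzScreenError):
    """A record or sequence fails a domain validity check."""


class UsageError(PdzScreenError):
    """An operation was invoked with arguments outside its contract."""
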