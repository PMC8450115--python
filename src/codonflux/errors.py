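"""Exception hierarchy shared across codonflux modules."""


class CodonFluxError(Exception):
    """Base class for all codonflux errors."""


class InputError(CodonFluxError):
    """Malformed or inconsistent user-supplied data."""


class ConfigurationError(CodonFluxError):
    """Invalid configuration, parameters, or reference tables."""


class UndefinedIndexError(CodonFluxError):
    """An index (CAI/CBI/tAI) is undefined for the given sequence."""


class EmptyResultError(CodonFluxError):
    """A computation retained no usable genes/records."""
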