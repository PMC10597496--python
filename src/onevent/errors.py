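"""Exception hierarchy shared across the package."""


class OnEventError(Exception):
    """Base class for all package errors."""


class InputError(OnEventError, ValueError):
    """Invalid user-supplied data (unsorted events, bad labels, ...)."""


class ConfigurationError(OnEventError, ValueError):
    """A parameter set violates its invariants or an unknown key was given."""


class InsufficientDataError(OnEventError, ValueError):
    """A computation needs more data than the inputs provide."""


class EmptyLibraryError(OnEventError, ValueError):
    """A frame library operation received or produced no frames."""


class ContractViolationError(OnEventError, RuntimeError):
    """An on-event function broke its contract (e.g. returned NST <= 0)."""
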