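"""Exception types raised across the package."""


class InvalidInputError(ValueError):
    """Input data violates a precondition (empty, mismatched, out of range)."""


class InsufficientDataError(RuntimeError):
    """A streaming buffer does not yet hold enough samples to produce output."""


class SessionOrderError(ValueError):
    """Trials arrived in an order the online session protocol forbids."""


class BalanceError(ValueError):
    """A side-balanced partition of trials was requested but is impossible."""
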