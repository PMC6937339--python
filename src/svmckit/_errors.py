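"""Package exception hierarchy."""


class SvmcError(Exception):
    """Base class for all svmckit errors."""


class InvalidInputError(SvmcError, ValueError):
    """Raised when an operation's preconditions are violated."""


class UnplayableJointError(SvmcError):
    """Raised when a session's target joint failed calibration (aROM too small)."""


class UnknownLabelError(SvmcError, KeyError):
    """Raised for channel/unit/sensor labels outside the frozen vocabulary."""
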