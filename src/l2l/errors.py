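"""Exception hierarchy for the l2l pipeline."""


class L2LError(Exception):
    """Base class for all l2l errors."""


class ParameterError(L2LError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateInputError(L2LError, ValueError):
    """Input is structurally empty or constant where structure is required."""


class CalibrationError(L2LError, ValueError):
    """Reflectance-probe calibration is invalid (M <= m)."""


class StateError(L2LError, RuntimeError):
    """Operation requires trained parameters or a checkpoint that is missing."""
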