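"""Exception types raised by ionowave."""


class IonowaveError(Exception):
    """Base class for all ionowave errors."""


class InvalidScenarioError(IonowaveError, ValueError):
    """A physical scenario violates its invariants."""


class ConfigurationError(IonowaveError, ValueError):
    """An acquisition/processing configuration is inconsistent (e.g. record too short)."""


class InvalidRequestError(IonowaveError, ValueError):
    """An operation was requested with arguments that make it meaningless."""


class DecompositionError(IonowaveError, ValueError):
    """A wavelet decomposition cannot be formed (depth vs. length, unknown family...)."""


class MeasurementError(IonowaveError, ValueError):
    """A trace does not support the requested measurement."""
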