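"""Exception hierarchy.

All user-facing failures derive from :class:`HeatSDError` so callers (and
the CLI) can distinguish bad inputs from genuine bugs.
"""


class HeatSDError(Exception):
    """Base class for all package errors."""


class InputError(HeatSDError, ValueError):
    """A caller supplied invalid data (bad series, index out of range, ...)."""


class ConfigurationError(HeatSDError, ValueError):
    """A parameter set or config file violates a declared invariant."""


class ComputationError(HeatSDError, RuntimeError):
    """The simulation produced an invalid value (NaN / negative flow)."""
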