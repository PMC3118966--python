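"""Exception hierarchy used across the package."""


class DMHError(Exception):
    """Base class for all package errors."""


class FormatError(DMHError, ValueError):
    """A file or table does not conform to the expected on-disk format."""


class InputError(DMHError, ValueError):
    """An in-memory argument violates an operation's precondition."""


class FitError(DMHError, RuntimeError):
    """A model or curve fit cannot be performed on the given data."""


class GenerationError(DMHError, ValueError):
    """A synthetic-data request is infeasible or inconsistent."""
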