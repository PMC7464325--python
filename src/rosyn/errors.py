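"""Exception types shared across the package."""


class RosynError(Exception):
    """Base class for all package errors."""


class ValidationError(RosynError, ValueError):
    """Input violates a documented precondition or type invariant."""


class ParseError(RosynError, ValueError):
    """A text input file could not be parsed; message names the line."""


class ConfigurationError(RosynError, ValueError):
    """A simulation or pipeline configuration is infeasible or malformed."""
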