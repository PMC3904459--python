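"""Exception hierarchy.

Two broad families matter to callers (and to the CLI exit codes):
validation problems with user input or configuration, and failures of the
computation itself (e.g. a dose level that is never crossed).
"""


class SobpkitError(Exception):
    """Base class for all package errors."""


class ValidationError(SobpkitError):
    """Invalid input, parameters or configuration (CLI exit code 2)."""


class ParameterError(ValidationError):
    """A physical or model parameter violates its invariant."""


class InputError(ValidationError):
    """A data input (grid, curve, file) is malformed."""


class ConfigurationError(ValidationError):
    """A run configuration is inconsistent (e.g. empty plateau)."""


class ParseError(InputError):
    """A text file could not be parsed; message names the offending line."""

    def __init__(self, path, line_no, message):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class ComputationError(SobpkitError):
    """The requested quantity could not be computed (CLI exit code 3)."""


class RangeUndefinedError(ComputationError):
    """The curve never crosses the requested dose level on its distal side."""
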