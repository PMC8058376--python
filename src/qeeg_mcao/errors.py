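"""Exception hierarchy shared across the package."""


class QeegError(Exception):
    """Base class for all package errors."""


class FormatError(QeegError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ParameterError(QeegError, ValueError):
    """A parameter violates an operation's precondition."""


class DegenerateDataError(QeegError, ValueError):
    """Input data is valid in form but degenerate for the requested
    computation (e.g. zero reference-band power, zero-variance sample)."""


class DesignError(QeegError, ValueError):
    """A statistical design is unsupported (e.g. unbalanced two-way layout)."""
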