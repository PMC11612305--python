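"""Exception hierarchy shared across the package."""


class ParencliticError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(ParencliticError, ValueError):
    """Invalid configuration; the message names the offending field."""


class ValidationError(ParencliticError, ValueError):
    """Data failed an invariant check (range, uniqueness, axis match)."""


class ParseError(ParencliticError, ValueError):
    """A file could not be parsed into the expected structure."""


class ConvergenceError(ParencliticError, RuntimeError):
    """An iterative procedure did not converge within its budget."""


class PipelineError(ParencliticError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
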