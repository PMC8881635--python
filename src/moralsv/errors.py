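"""Exception hierarchy.

``ValidationError`` signals bad inputs/configuration (CLI exit code 1);
any other failure during a pipeline stage is wrapped in ``PipelineError``
(CLI exit code 2).
"""


class MoralsvError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MoralsvError, ValueError):
    """Raised when inputs or configuration violate a documented precondition."""


class PipelineError(MoralsvError, RuntimeError):
    """Raised when a pipeline stage fails at run time."""
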