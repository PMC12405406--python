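"""Exception hierarchy for the toolkit.

All toolkit errors derive from :class:`BeamQAError` so callers (and the CLI)
can distinguish analysis failures from configuration mistakes.
"""


class BeamQAError(Exception):
    """Base class for all toolkit errors."""


class InputError(BeamQAError, ValueError):
    """Invalid argument values or violated preconditions."""


class DegenerateModelError(InputError):
    """A model or curve collapsed to zero dose and cannot be normalized."""


class FormatError(BeamQAError, ValueError):
    """A file does not conform to one of the documented dialects."""


class UnsupportedDialectError(FormatError):
    """The file is recognizable but uses an unsupported variant."""


class ResourceError(BeamQAError):
    """The request exceeds a configured size limit."""


class EmptyEvaluationError(BeamQAError):
    """No points survived masking; there is nothing to summarize."""


class ConfigError(BeamQAError):
    """A run configuration contains unknown or inconsistent entries."""
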