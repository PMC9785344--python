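"""Exception types shared across the toolkit."""


class NoduleseqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NoduleseqError):
    """A generator or pipeline configuration field is invalid."""


class InputError(NoduleseqError):
    """An input table or sequence set violates a precondition."""


class ConsistencyError(NoduleseqError):
    """Two inputs that must agree (e.g. truth vs count matrix) do not."""


class DegenerateInputError(NoduleseqError):
    """Input is structurally valid but degenerate for the requested operation."""


class DesignError(NoduleseqError):
    """The sample design cannot support the requested contrast."""
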