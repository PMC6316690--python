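"""Package-level exception types."""


class RicenetError(Exception):
    """Base class for all ricenet errors."""


class ConfigurationError(RicenetError, ValueError):
    """An invalid parameter or simulation configuration."""


class EmptyMatrixError(RicenetError, ValueError):
    """An operation produced or received a matrix with no usable genes."""


class InputError(RicenetError, ValueError):
    """Invalid data passed to an analysis operation."""
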