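"""Exception types shared across the package."""


class E3PrioError(Exception):
    """Base class for package errors."""


class InputError(E3PrioError, ValueError):
    """A caller supplied an invalid value (empty symbol, malformed row, ...)."""


class ConfigError(E3PrioError, ValueError):
    """A configuration value is inconsistent or out of range."""


class NotFoundError(E3PrioError, KeyError):
    """A requested symbol is absent from the catalog or edge set."""
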