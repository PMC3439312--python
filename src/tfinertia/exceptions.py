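"""Error taxonomy shared across the package.

All errors raised on bad user input derive from :class:`ValueError` so that
callers embedding the library can catch them uniformly; the CLI maps each
subclass to a distinct exit code.
"""


class ConfigError(ValueError):
    """A configuration file or parameter set is invalid or incomplete."""


class DataError(ValueError):
    """An input table violates a structural precondition."""


class NumericalError(RuntimeError):
    """A numerical routine failed to produce a usable result."""
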