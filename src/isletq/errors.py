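"""Exception hierarchy shared across the pipeline."""


class IsletqError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(IsletqError, ValueError):
    """A configuration value violates its documented invariant."""


class DegenerateSignalError(IsletqError, ValueError):
    """A measurement carries no usable signal (e.g. zero channel sum)."""


class InsufficientDataError(IsletqError, ValueError):
    """Too few observations for the requested statistic."""


class SchemaError(IsletqError, ValueError):
    """A table is missing required columns."""

    def __init__(self, path, missing):
        self.path = path
        self.missing = list(missing)
        super().__init__(
            f"{path}: missing required column(s): {', '.join(self.missing)}"
        )


class ParseError(IsletqError, ValueError):
    """A file could not be parsed; names the offending file."""
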