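"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """Inputs violate a documented precondition."""


class MissingChannelError(ValidationError):
    """A required montage channel is absent from a recording."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(f"missing required channels: {', '.join(self.missing)}")


class EDFError(IOError):
    """An EDF file could not be read or is structurally invalid."""


class UnsupportedFormatError(EDFError):
    """The file is valid EDF but uses a feature this reader does not support."""


class MontageError(ValidationError):
    """A channel has no known scalp position or region assignment."""
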