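"""Exception hierarchy for the electrome package."""


class ElectromeError(Exception):
    """Base class for all package errors."""


class ParameterError(ElectromeError, ValueError):
    """An argument is outside its valid domain."""


class ConfigError(ElectromeError, ValueError):
    """A profile, design or run configuration is invalid."""


class FormatError(ElectromeError, ValueError):
    """A series or manifest file cannot be parsed."""


class DegenerateInputError(ElectromeError, ValueError):
    """Input is structurally valid but statistically degenerate
    (e.g. zero variance where a variance is required)."""
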