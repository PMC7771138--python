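"""Exception hierarchy for table loading and analysis contracts."""


class TraitgradError(Exception):
    """Base class for all package errors."""


class SchemaError(TraitgradError):
    """A table is missing a required column or carries an unknown one."""


class ValidationError(TraitgradError):
    """A table or config violates a value-level invariant."""


class ConfigError(TraitgradError):
    """An analysis or simulation configuration is invalid."""


class InsufficientDataError(TraitgradError):
    """Too few observations to run the requested statistic."""
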