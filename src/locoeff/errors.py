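"""Exception types shared across the pipeline."""


class SchemaError(KeyError):
    """An input table is missing required columns."""


class ConfigurationError(ValueError):
    """A configuration value is invalid or inconsistent with the data."""


class UndefinedChangeError(ZeroDivisionError):
    """Percentage change is undefined because the base weekly load is zero."""


class SubsetTooSmallError(ValueError):
    """A readiness subset has too few players, rows or occupied categories to fit."""
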