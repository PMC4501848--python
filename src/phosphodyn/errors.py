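"""Exception types shared across the pipeline stages."""


class PhosphodynError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PhosphodynError, ValueError):
    """An input table does not conform to the declared dialect."""


class ParameterError(PhosphodynError, ValueError):
    """A stage parameter is outside its valid domain."""


class InsufficientDataError(PhosphodynError, ValueError):
    """Too few observations to compute the requested quantity."""


class FitUndefinedError(PhosphodynError, ValueError):
    """A model fit cannot be defined on the available points."""


class DataIntegrityError(PhosphodynError, ValueError):
    """Cross-stage inputs are mutually inconsistent."""
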