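"""Exception taxonomy shared by all grnkit modules."""


class GrnkitError(Exception):
    """Base class for all grnkit errors."""


class FormatError(GrnkitError):
    """A file could not be parsed as the expected format."""


class ValidationError(GrnkitError):
    """Parsed content violates a domain invariant."""


class DimensionError(ValidationError):
    """Inputs have inconsistent shapes."""


class UsageError(GrnkitError):
    """The caller asked for something the API does not support."""


class StaleRecordError(GrnkitError):
    """A stored perturbation record no longer matches its inputs on disk."""
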