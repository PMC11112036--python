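"""Exception types shared across the pipeline."""


class StripMEAError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StripMEAError, ValueError):
    """A parameter or config value violates its contract."""


class FormatError(StripMEAError, ValueError):
    """An on-disk file is malformed or inconsistent with its sidecar."""


class RangeError(StripMEAError, ValueError):
    """A value cannot be represented in the requested on-disk dtype."""


class ContractError(StripMEAError, ValueError):
    """An input violates a documented precondition (e.g. unsorted spike times)."""
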