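"""Exception hierarchy shared across the package."""


class NicheDomainsError(Exception):
    """Base class for package errors."""


class ConfigurationError(NicheDomainsError):
    """Invalid configuration or parameters."""


class DataError(NicheDomainsError):
    """Inputs that are structurally valid but scientifically unusable."""
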