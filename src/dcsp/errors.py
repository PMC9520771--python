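"""Exception hierarchy shared across the package."""


class DCSPError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DCSPError):
    """A file did not conform to its expected dialect."""


class ValidationError(DCSPError):
    """An in-memory object violated a structural invariant."""


class ConfigError(DCSPError):
    """A run configuration is missing or malformed."""


class NetworkSupportError(DCSPError):
    """A gene set has no support in the interaction network."""


class DisconnectedPathwayError(DCSPError):
    """No drug target is a pathway member and no pathway gene reaches a target."""
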