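"""Exception hierarchy."""


class OirdlabError(Exception):
    """Base class for all package errors."""


class ConfigError(OirdlabError):
    """Invalid configuration value; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class RecordValidationError(OirdlabError):
    """A visit record violates an invariant; the message lists visit ids."""


class FitError(OirdlabError):
    """Model fitting cannot proceed (e.g. all-abstain label matrix)."""
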