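"""Exception hierarchy shared across the package."""


class KneespringError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(KneespringError):
    """A required piece of configuration is missing or malformed."""


class ValidationError(KneespringError, ValueError):
    """An input violates a documented contract or invariant."""


class InstabilityError(KneespringError):
    """No force balance exists inside the dislocation limit."""


class UnstableTrialError(KneespringError):
    """Every gait cycle of a trial was flagged unstable."""


class TuningFailureError(KneespringError):
    """A tuning stage could not select any stable spring candidate."""
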