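"""Exception hierarchy."""


class PhiSpectrumError(Exception):
    """Base class for package errors."""


class FormatError(PhiSpectrumError):
    """Malformed transition table / dense matrix / state string."""


class StateError(PhiSpectrumError):
    """Invalid system state (wrong length, non-binary values, ...)."""


class CombinatorialGuardError(PhiSpectrumError):
    """An enumeration would exceed the configured cap; aborting instead of truncating."""
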