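"""Exception hierarchy for monoseize."""


class MonoseizeError(Exception):
    """Base class for all monoseize errors."""


class EdfFormatError(MonoseizeError):
    """Raised for unreadable, truncated or inconsistent EDF files."""


class SamplingRateError(MonoseizeError):
    """Raised when a recording's sampling rate violates an expectation."""


class MontageError(MonoseizeError):
    """Raised when a bipolar derivation references a missing electrode."""


class ChannelSelectionError(MonoseizeError):
    """Raised for invalid channel-subset policies or missing channels."""


class AnnotationError(MonoseizeError):
    """Raised for invalid seizure annotations (inverted/overlapping intervals)."""
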