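"""Exception hierarchy.

Every error the package raises deliberately derives from ContactStimError so
callers (and the CLI exit-code mapping) can distinguish error classes without
string matching.
"""


class ContactStimError(Exception):
    """Base class for all contactstim errors."""


class ConfigurationError(ContactStimError):
    """Invalid session configuration, region geometry, or parameter coupling."""


class UnsupportedSchemaError(ConfigurationError):
    """Config file uses a schema version this package does not understand."""


class StreamError(ContactStimError):
    """Malformed landmark stream (e.g. out-of-order timestamps)."""


class TruncationError(StreamError):
    """Frame source ended before covering the session duration.

    Carries ``last_covered_s``, the timestamp of the last frame seen.
    """

    def __init__(self, last_covered_s: float, required_s: float):
        self.last_covered_s = last_covered_s
        self.required_s = required_s
        super().__init__(
            f"frame source ended at t={last_covered_s:.3f}s but the session "
            f"requires coverage up to t={required_s:.3f}s"
        )


class LogParseError(ContactStimError):
    """Malformed session log."""


class ReplayMismatchError(ConfigurationError):
    """Replay was attempted with a config whose hash differs from the log header."""


class AnalysisError(ContactStimError):
    """Invalid input to the single-case analysis layer."""


class UndefinedAgreementError(AnalysisError):
    """Agreement percentage requested with zero observations (0/0)."""


class ScreeningError(AnalysisError):
    """Preference screening tally with fewer than the minimum presentations."""


class ActuatorError(ContactStimError):
    """An output device failed; sessions treat this as fail-open."""
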