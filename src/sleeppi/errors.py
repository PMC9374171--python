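"""Exception types shared across the pipeline."""


class SleepPIError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SleepPIError):
    """An invalid configuration value; the message names the offending field."""


class ScoringError(SleepPIError):
    """A questionnaire could not be scored (missing or out-of-range item)."""
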