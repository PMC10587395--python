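"""Exception hierarchy for emodecode."""


class EmodecodeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EmodecodeError):
    """Invalid or inconsistent configuration."""


class ScheduleInfeasibleError(ConfigurationError):
    """Requested trial schedule does not fit in the run duration."""


class DesignDegenerateError(EmodecodeError):
    """Design matrix is rank deficient or otherwise unusable."""


class InsufficientDataError(EmodecodeError):
    """Too few trials, classes, runs or subjects for the requested analysis."""


class ValidationError(EmodecodeError):
    """A file or table failed schema validation."""
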