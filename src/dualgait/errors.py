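"""Exception hierarchy shared across the package."""


class DualgaitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DualgaitError):
    """A domain object violates one of its invariants.

    Carries the name of the offending field where known.
    """

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class ConfigurationError(DualgaitError):
    """A configuration value is out of range or internally inconsistent."""


class SchemaVersionError(ValidationError):
    """A persisted record declares an unknown schema version."""


class SessionParseError(DualgaitError):
    """A session file line could not be parsed as JSON."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class DegenerateGeometryError(DualgaitError):
    """Joint geometry is degenerate (e.g. a zero-length limb segment)."""


class MissingFeatureError(DualgaitError):
    """A feature cannot be computed from the available phase data."""

    def __init__(self, feature: str, reason: str = ""):
        msg = f"feature '{feature}' cannot be computed"
        if reason:
            msg += f": {reason}"
        super().__init__(msg)
        self.feature = feature


class IncompleteTrialError(DualgaitError):
    """A trial is missing at least one feature; callers may drop the trial."""

    def __init__(self, feature: str, subject_id: str, trial_index: int):
        super().__init__(
            f"trial {trial_index} of subject {subject_id}: "
            f"missing feature '{feature}'"
        )
        self.feature = feature
        self.subject_id = subject_id
        self.trial_index = trial_index


class RuleInapplicableError(DualgaitError):
    """A distractor rule would reproduce the correct answer; resample."""


class DegenerateFitError(DualgaitError):
    """Regression targets are degenerate (e.g. constant)."""


class SchemaError(DualgaitError):
    """Feature columns do not match what a fitted model expects."""
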