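"""Exception hierarchy for cohort I/O, validation and evaluation."""


class CopdEmrError(Exception):
    """Base class for all package-specific errors."""


class ChartParseError(CopdEmrError):
    """A chart record could not be parsed.

    Carries the 1-based line number and the offending field so callers can
    point users at the exact record in a JSON Lines file.
    """

    def __init__(self, line_number: int, field: str, message: str):
        self.line_number = line_number
        self.field = field
        super().__init__(f"line {line_number}, field '{field}': {message}")


class ChartValidationError(CopdEmrError):
    """A parsed chart violates a data-model invariant (e.g. event before birth)."""


class CohortIntegrityError(CopdEmrError):
    """A cohort-level invariant is violated (e.g. duplicate patient_id)."""


class EvaluationError(CopdEmrError):
    """Evaluation against the reference standard cannot proceed
    (missing reference labels, id mismatch, empty cohort)."""


class UndefinedMetricError(CopdEmrError):
    """A metric is undefined for the given counts (e.g. n = 0)."""


class DiscordanceContractError(CopdEmrError):
    """Discordance categorization was called on a concordant prediction."""


class ConfigError(CopdEmrError):
    """A lexicon/algorithm/run configuration file is invalid."""
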