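"""Exception hierarchy for surveysel."""


class SurveySelError(Exception):
    """Base class for all surveysel errors."""


class ConfigurationError(SurveySelError):
    """A column-role configuration or operation configuration is invalid."""


class ParseError(SurveySelError):
    """A table cell could not be parsed; carries row/column context."""


class EmptyDatasetError(SurveySelError):
    """An operation removed every record."""


class DegenerateSplitError(SurveySelError):
    """A train/validation half has no cases or no non-cases."""


class ConvergenceError(SurveySelError):
    """An iterative estimator failed to converge.

    The last iterate, when available, is attached as ``last_iterate``.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class SeparationError(SurveySelError):
    """A logistic fit diverged, typically due to separation; names the term."""


class DesignError(SurveySelError):
    """The survey design cannot support variance estimation (e.g. single-PSU strata)."""
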