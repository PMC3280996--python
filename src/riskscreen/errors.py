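"""Exception types raised across the package."""


class RiskscreenError(Exception):
    """Base class for all package errors."""


class CohortSchemaError(RiskscreenError):
    """A cohort file or frame violates the cohort schema; the message names
    the offending column and, where applicable, row."""


class ConvergenceError(RiskscreenError):
    """A proportional-hazards fit failed to converge, typically because of a
    monotone partial likelihood (perfect separation)."""


class NoSplitError(RiskscreenError):
    """Age cut-point search is impossible: no events, or all ages equal."""


class ToolBuildError(RiskscreenError):
    """Tool assembly produced no items."""


class ScoringError(RiskscreenError):
    """A subject record is missing a field required by a tool item."""


class DegenerateTableError(RiskscreenError):
    """A contingency table has a zero cell that makes a statistic undefined."""


class UndefinedValueError(RiskscreenError):
    """A formula's denominator vanished for the supplied arguments."""
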