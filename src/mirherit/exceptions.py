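"""Exception hierarchy for mirherit."""


class MirheritError(Exception):
    """Base class for all mirherit errors."""


class ParameterError(MirheritError, ValueError):
    """A configuration or argument value violates its contract."""


class UndefinedScoreError(MirheritError, ValueError):
    """RE-score requested for an empty effective target or non-target set."""


class EmptyResultError(MirheritError, ValueError):
    """An operation removed every row/column and nothing remains to report."""


class SingularDesignError(MirheritError, ValueError):
    """A regression design matrix is singular (e.g. constant predictor)."""


class UndefinedCorrelationError(MirheritError, ValueError):
    """Correlation requested for a constant vector."""


class DependencyError(MirheritError, RuntimeError):
    """A pipeline stage is missing an upstream output."""
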