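"""Exception hierarchy for swqus.

Everything derives from :class:`SwqusError` so callers can catch the
package's failures with a single ``except``; most classes also derive from
``ValueError`` because they signal invalid inputs.
"""


class SwqusError(Exception):
    """Base class for all swqus errors."""


class InvalidTissueError(SwqusError, ValueError):
    """A tissue model violates a physical invariant (e.g. E <= 0)."""


class InvalidSignalError(SwqusError, ValueError):
    """A signal is unusable for estimation (e.g. non-positive displacement maxima)."""


class DegeneratePropagationError(SwqusError, ValueError):
    """Time-to-peak profile carries no usable propagation (zero/negative slope)."""


class EstimationError(SwqusError, ValueError):
    """An estimator could not produce a value (e.g. all beam pairs excluded)."""


class InsufficientDataError(SwqusError, ValueError):
    """Too few observations for the requested fit."""


class AlignmentError(SwqusError, ValueError):
    """Two spectra/frames do not share compatible axes."""


class FitError(SwqusError, ValueError):
    """A least-squares fit has too few points inside the requested band."""


class UndefinedCorrelationError(SwqusError, ValueError):
    """Pearson correlation undefined (zero variance input)."""


class DegenerateRocError(SwqusError, ValueError):
    """ROC analysis requested with a single-class label vector."""


class SplitError(SwqusError, ValueError):
    """A cross-validation split would leave fewer than two holdout subjects."""


class ConfigError(SwqusError, ValueError):
    """A generator/sequence configuration is infeasible."""
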