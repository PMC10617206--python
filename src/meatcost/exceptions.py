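"""Exception hierarchy shared across the package.

All errors derive from :class:`MeatCostError` so callers can catch the
package's failures with a single ``except``.  Subclasses distinguish
configuration problems (bad run configs, missing strata) from data problems
(invalid parameters, empty inputs, infeasible calibrations), which the CLI
maps to distinct exit codes.
"""


class MeatCostError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MeatCostError, ValueError):
    """A numeric argument violates its domain (e.g. non-positive RR)."""


class EmptyInputError(MeatCostError, ValueError):
    """An operation received an empty record set or draw matrix."""


class AlignmentError(MeatCostError, ValueError):
    """Prevalence vectors / RR vectors do not share a category indexing."""


class AggregationError(MeatCostError, ValueError):
    """Sex-combination requested with a missing sex stratum."""


class CalibrationError(MeatCostError, ValueError):
    """Requested survey marginals are infeasible (non-monotone tails...)."""


class InsufficientDataError(MeatCostError, ValueError):
    """Too few observations to fit the cost trend."""


class DegenerateDesignError(MeatCostError, ValueError):
    """Regression design matrix is singular (constant year values)."""


class ConfigurationError(MeatCostError):
    """A run configuration is incomplete or internally inconsistent."""
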