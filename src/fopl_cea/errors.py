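"""Exception hierarchy for the pipeline.

Validation failures (bad config, bad inputs) are distinguished from model
failures (a parameter draw pushing a rate outside its valid range) so the
CLI can map them to different exit codes and the PSA can count, rather
than silently drop, failed iterations.
"""


class FoplCeaError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(FoplCeaError):
    """A configuration value violates its invariant."""


class InvalidInputError(FoplCeaError):
    """An input table or argument violates its contract."""


class DegenerateVarianceError(InvalidInputError):
    """Paired differences have zero variance; the t statistic is undefined."""


class UndefinedScalingError(InvalidInputError):
    """Mandatory-scenario scaling requested for a category with zero uptake
    but a nonzero voluntary effect."""


class InvalidPairingError(InvalidInputError):
    """Two life-table runs do not share the same cohort structure."""


class ModelConsistencyError(FoplCeaError):
    """A simulated rate left [0, 1); the parameter combination is outside
    the model's domain of validity."""


class RateOverflowError(ModelConsistencyError):
    """Annual transition rates too large: a disease state went negative."""


class ValidationError(InvalidInputError):
    """Input-table schema/invariant validation failed.

    Carries the full list of violations so callers can report every
    problem at once.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "input validation failed with %d violation(s):\n%s"
            % (len(self.violations), "\n".join("  - " + v for v in self.violations))
        )
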