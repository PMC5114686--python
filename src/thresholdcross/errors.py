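"""Typed errors raised across the package."""


class ThresholdCrossError(Exception):
    """Base class for all package errors."""


class InfeasibleDesignError(ThresholdCrossError):
    """The effective standardized effect is non-positive.

    Raised when a conservative threshold rule eats the whole assumed
    treatment effect, so no finite single-arm sample size can attain the
    target power. Scenario grids catch this to record the cell as
    infeasible instead of aborting.
    """


class CohortCSVError(ThresholdCrossError):
    """A historical-cohort CSV file violates the expected schema."""


class ConfigError(ThresholdCrossError):
    """A run configuration file is invalid or inconsistent."""
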