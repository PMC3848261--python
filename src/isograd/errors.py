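"""Exception hierarchy for isograd.

All package-specific failures derive from :class:`IsogradError` so callers
can catch a single base class at the CLI boundary.
"""


class IsogradError(Exception):
    """Base class for all isograd errors."""


class DomainError(IsogradError, ValueError):
    """An argument is outside the mathematical domain of an operation
    (e.g. non-positive eluent concentration, negative time)."""


class DegenerateDesignError(IsogradError, ValueError):
    """Too few distinct calibration concentrations to fit the quadratic
    retention model (at least three are required)."""


class InvalidRetentionError(IsogradError, ValueError):
    """A calibration retention time does not exceed the void time, so the
    retention factor k = (tR - t0)/t0 would be non-positive."""


class NoElutionError(IsogradError, RuntimeError):
    """The gradient integral never reaches the void time within the
    configured elution cap: the analyte does not elute."""


class InconsistentModelError(IsogradError, ValueError):
    """Predicted peak-marker times violate fronting < apex < tailing."""


class InsufficientDataError(IsogradError, ValueError):
    """A lookup table has too few rows for interpolation."""


class NoSolutionError(IsogradError, ValueError):
    """The peak-shape parameter solve could not bracket a root (degenerate
    asymmetry ratio)."""


class InvalidPeakError(IsogradError, ValueError):
    """A peak has a zero or negative half-height width."""


class InfeasibleInitializationError(IsogradError, ValueError):
    """The initial simplex collapses to zero volume after clamping to the
    concentration bounds."""


class DegenerateStartError(IsogradError, RuntimeError):
    """Every initial simplex vertex is infeasible (infinite criterion)."""


class DegeneratePopulationError(IsogradError, RuntimeError):
    """The entire genetic population is infeasible after the initial cull."""


class ConfigError(IsogradError, ValueError):
    """Invalid optimizer or run configuration."""
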