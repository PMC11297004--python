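"""Exception hierarchy for the landscape toolkit."""


class PelkitError(Exception):
    """Base class for all toolkit errors."""


class ContractViolation(PelkitError):
    """Caller violated a documented precondition (e.g. dimension mismatch)."""


class DegenerateGeometryError(PelkitError):
    """Configuration is degenerate for the potential (e.g. coincident beads)."""


class PotentialEvaluationError(PelkitError):
    """An external or built-in potential failed to evaluate.

    Carries the offending configuration in ``configuration``.
    """

    def __init__(self, message, configuration=None):
        super().__init__(message)
        self.configuration = configuration


class ConvergenceError(PelkitError):
    """An iterative optimisation failed to converge.

    ``trajectory_tail`` holds the last few iterates for diagnosis.
    """

    def __init__(self, message, trajectory_tail=None):
        super().__init__(message)
        self.trajectory_tail = trajectory_tail or []


class RejectedCandidateError(PelkitError):
    """A transition-state candidate converged to a minimum (no negative mode)."""


class HigherOrderSaddleError(PelkitError):
    """A stationary point retained more than one negative Hessian eigenvalue."""


class UnconvergedPointError(PelkitError):
    """A stationary point does not meet database-grade convergence."""


class UnreachableError(PelkitError):
    """Two minima are not connected in the transition network."""


class MissingRepresentativeError(PelkitError):
    """No minimum falls in a requested order-parameter band."""

    def __init__(self, band_name, band):
        super().__init__(
            f"no minimum with order parameter in {band} ({band_name} band)"
        )
        self.band_name = band_name
        self.band = band


class NotAssessableError(PelkitError):
    """Convergence cannot be assessed (fewer than two snapshots)."""


class EmptyStructureError(PelkitError):
    """A structure file contains no RNA residues."""


class PdbParseError(PelkitError):
    """A PDB record could not be parsed; ``line_number`` locates it."""

    def __init__(self, message, line_number=None):
        super().__init__(message)
        self.line_number = line_number


class MissingAtomError(PelkitError):
    """A descriptor requires an atom that is absent from the residue."""


class BracketOverflowError(PelkitError):
    """A pair set needs more than four bracket tiers in dot-bracket notation."""


class UndefinedCorrelationError(PelkitError):
    """Rank correlation undefined (constant energy vector)."""


class InterpolationError(PelkitError):
    """A band image has an unrepairable steric clash; ``image`` names it."""

    def __init__(self, message, image=None):
        super().__init__(message)
        self.image = image


class ConfigError(PelkitError):
    """A configuration or database file violates its schema."""
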