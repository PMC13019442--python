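"""Exception hierarchy for the dbfe package."""


class DBFEError(Exception):
    """Base class for all dbfe errors."""


class FormatError(DBFEError):
    """A structure or trajectory file could not be parsed."""


class ParameterizationError(DBFEError):
    """Lennard-Jones parameters missing or invalid for an atom."""


class TopologyError(DBFEError):
    """Atom-count or connectivity mismatch between topology and data."""


class EmptyTrajectoryError(DBFEError):
    """A trajectory source contained no frames."""


class InsufficientDataError(DBFEError):
    """Too few frames survive burn-in/decorrelation to continue."""


class DegenerateGeometryError(DBFEError):
    """Point set is collinear or otherwise unfit for superposition."""


class ClusteringError(DBFEError):
    """Mode detection failed (e.g. all clusters singleton)."""


class DegenerateFitError(DBFEError):
    """Restraint fit impossible (rank-deficient scatter, too few members)."""


class ConcentrationOverflowError(DBFEError):
    """Bingham rejection sampling acceptance rate collapsed."""


class QuadratureError(DBFEError):
    """Numerical integration failed to reach the requested tolerance."""


class ParameterError(DBFEError):
    """Invalid user-supplied parameter value."""


class NoOverlapError(DBFEError):
    """No decoupled sample passed the clash filter (alpha = 0).

    Mirrors the failure mode where the binding site closes during the
    receptor-only simulation and no combinatorial sample fits the pocket.
    """


class EstimatorError(DBFEError):
    """Free-energy estimator failed to converge."""


class EnergyEvaluationError(DBFEError):
    """An energy backend failed on a frame."""


class AssemblyError(DBFEError):
    """A free-energy leg is NaN or infinite at assembly time."""


class SamplerError(DBFEError):
    """Monte-Carlo sampler pathology (acceptance rate, divergence)."""
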