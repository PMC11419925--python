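"""Exception hierarchy shared across the package."""


class HemelockError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(HemelockError):
    """A coordinate record could not be parsed; message names the line."""


class TopologyMismatchError(HemelockError):
    """Models of a multi-model file do not share one atom topology."""


class SelectionError(HemelockError):
    """An atom selection resolved to an unusable atom set."""


class DegenerateGeometryError(HemelockError):
    """Superposition attempted on <3 atoms or a collinear point set."""


class UnresolvedGeometryError(HemelockError):
    """A required donor/acceptor/antecedent atom has no coordinates."""


class ContractViolation(HemelockError):
    """An operation was called outside its documented preconditions."""


class DegenerateFitError(HemelockError):
    """A regression panel carries no usable variation."""


class FitConvergenceError(HemelockError):
    """A nonlinear fit failed to converge; message reports start values."""
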