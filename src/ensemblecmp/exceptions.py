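"""Exception hierarchy shared by all ensemblecmp modules."""


class EnsembleCmpError(Exception):
    """Base class for all errors raised by ensemblecmp."""


class FormatError(EnsembleCmpError):
    """A file could not be parsed in the expected format."""


class SelectionError(EnsembleCmpError):
    """An atom selection resolved to zero atoms or is otherwise invalid."""


class TopologyError(EnsembleCmpError):
    """Atom counts or ordering are inconsistent across inputs."""


class ShapeError(EnsembleCmpError):
    """Array dimensions of two operands do not match."""


class DataError(EnsembleCmpError):
    """Input values are outside the admissible domain (negative, non-finite...)."""


class InsufficientDataError(DataError):
    """Too few frames/points for the requested estimate."""


class NumericalError(EnsembleCmpError):
    """A numerically degenerate input (singular covariance, collinear atoms...)."""


class InputError(EnsembleCmpError):
    """Invalid argument combination for a workflow operation."""
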