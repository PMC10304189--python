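"""Exception hierarchy shared across the package."""


class VibrafragError(Exception):
    """Base class for all package errors."""


class MalformedInputError(VibrafragError):
    """A file or table violates its format contract (missing tag, bad count line...)."""


class InvalidArgumentError(VibrafragError, ValueError):
    """A caller-supplied argument violates a precondition."""


class PeriodicPolymerError(VibrafragError):
    """A covalent component wraps around the cell: not a molecular crystal."""


class UndefinedDihedralError(VibrafragError):
    """Central atoms of a dihedral quad are collinear."""


class IncompleteShellError(VibrafragError):
    """Central molecule too close to the supercell boundary for a complete H-bond shell."""


class ConjugationCutError(VibrafragError):
    """Fragment interception would sever a bond inside a conjugated system."""


class MissingParameterError(VibrafragError):
    """The toy force field lacks a term for a bonded pair or angle in the topology."""


class ConvergenceError(VibrafragError):
    """Geometry optimization exhausted max_steps. Carries the last geometry."""

    def __init__(self, message, last_model=None, report=None):
        super().__init__(message)
        self.last_model = last_model
        self.report = report
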