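"""Exception hierarchy for pathsem."""


class PathsemError(Exception):
    """Base class for all pathsem errors."""


class IncomparableEvidenceError(PathsemError):
    """Raised when peptide-set evidence is compared against interval evidence."""


class CyclicEvidenceError(PathsemError):
    """Raised when mutual sequence containment at equal mass would create a
    degradation cycle."""


class ModelSpecError(PathsemError):
    """Malformed model structure or model-grammar text."""


class IdentificationError(PathsemError):
    """Model has more free parameters than distinct covariance moments."""


class NotPositiveDefiniteError(PathsemError):
    """A covariance matrix that must be positive definite is not."""


class SingularStructureError(PathsemError):
    """I - B is singular: a feedback loop with unit gain."""
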