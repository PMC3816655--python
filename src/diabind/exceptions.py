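"""Exception hierarchy for diabind."""


class DiabindError(Exception):
    """Base class for all diabind errors."""


class ParameterError(DiabindError, ValueError):
    """Invalid or non-finite force-field / model parameter."""


class DomainError(DiabindError, ValueError):
    """Input outside the mathematical domain of an operation (e.g. r <= 0)."""


class ConfigurationError(DiabindError, ValueError):
    """Inconsistent run configuration (empty ligand, no dihedrals, ...)."""


class EmptyEnsembleError(DiabindError, ValueError):
    """An operation requiring at least one frame received none."""


class ShapeError(DiabindError, ValueError):
    """Mismatched array shapes between related inputs."""


class CoverageError(DiabindError, ValueError):
    """A per-atom map does not cover every atom it must."""


class FeatureError(DiabindError, KeyError):
    """A model requires a feature the input does not provide."""


class CollinearityError(DiabindError, ValueError):
    """Rank-deficient least-squares design matrix."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; offending columns: "
            + ", ".join(self.columns)
        )


class UndefinedCorrelationError(DiabindError, ValueError):
    """Pearson correlation undefined (zero variance input)."""


class GenerationError(DiabindError, RuntimeError):
    """Synthetic fixture generation failed (e.g. impossible packing)."""


class StructureError(DiabindError, ValueError):
    """Problem reading or interpreting a structure/trajectory file."""
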