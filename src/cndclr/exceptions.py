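"""Exception hierarchy for the CND-clr pipeline."""


class CndError(ValueError):
    """Base class for all pipeline errors."""


class CompositionError(CndError):
    """A concentration is missing, non-positive, or otherwise invalid."""


class InfeasibleCompositionError(CompositionError):
    """Nutrient mass meets or exceeds the total dry matter, leaving no filler."""


class SchemaError(CndError):
    """A frame or norms object is missing required components or columns."""


class GroupSizeError(CndError):
    """A group is too small for the requested computation."""


class SingularCovarianceError(CndError):
    """The covariance (or within-group scatter) matrix is not invertible."""


class ZeroVarianceError(CndError):
    """A component or variable has no variance where variance is required."""
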