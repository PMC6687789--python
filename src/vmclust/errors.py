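"""Exception hierarchy for vmclust."""


class VmclustError(Exception):
    """Base class for all vmclust errors."""


class FormatError(VmclustError):
    """A file does not conform to the expected text format."""


class ValidationError(VmclustError):
    """Input data violates a documented precondition or invariant."""


class UndefinedIndexError(VmclustError):
    """A cluster validity index is undefined for the given partition.

    Raised when the C-Index denominator vanishes (all pairwise distances
    equal, or a single cluster) or when no within-cluster pair exists
    (all-singleton partition).
    """


class UnclassifiableShapeError(VmclustError):
    """A cluster profile matches none of the shape categories.

    Happens for degenerate (flat) aggregate curves; resolve with a
    manual override mapping.
    """
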