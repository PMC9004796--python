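"""Exception hierarchy.

Validation problems (bad files, mismatched annotations, impossible requests)
and numerical failures (degenerate dispersion, non-positive update ratios)
are kept distinct so the command-line layer can map them to exit codes 2
and 3 respectively.
"""


class ResetError(Exception):
    """Base class for all errors raised by resetlib."""

    exit_code = 1


class ValidationError(ResetError):
    """Invalid inputs: malformed files, inconsistent identifiers, bad sizes."""

    exit_code = 2


class AnnotationMismatchError(ValidationError):
    """A sample referenced by an annotation is absent from the matrix (or vice versa)."""


class DegenerateGroupError(ValidationError):
    """A cell-type group is empty or too small for the requested statistic."""


class InsufficientGroupsError(ValidationError):
    """Fewer than two cell types; between-group dispersion is undefined."""


class LibraryTooSmallError(ValidationError):
    """A reference library with fewer than two CpGs cannot support leave-one-out scores."""


class InsufficientPoolError(ValidationError):
    """More CpGs requested than the candidate pool or matrix provides."""


class NumericError(ResetError):
    """Numerical failure during computation."""

    exit_code = 3


class DegenerateDispersionError(NumericError):
    """Minimum within-cell-type dispersion is zero, so the DSC ratio is undefined.

    This arises from duplicated samples or single-sample groups; treating it
    as +inf would let the stochastic search diverge, so it is an error.
    """
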