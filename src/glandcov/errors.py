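"""Exception hierarchy.

Every user-facing failure mode raises a named subclass of :class:`GlandcovError`
so callers (and the CLI) can fail fast with a specific category instead of a
bare ``ValueError``. No function in this package silently imputes, drops or
regularizes data.
"""


class GlandcovError(Exception):
    """Base class for all errors raised by glandcov."""


class NewickParseError(GlandcovError):
    """The input could not be parsed as a single rooted Newick tree."""


class MissingBranchLengthError(NewickParseError):
    """An edge of the tree has no branch length."""


class DuplicateTipLabelError(NewickParseError):
    """Two or more tips carry the same label."""


class MissingTaxonError(GlandcovError):
    """Requested taxa are absent from the tree (or vice versa)."""

    def __init__(self, missing, where="tree"):
        self.missing = sorted(missing)
        super().__init__(f"taxa not found in {where}: {', '.join(self.missing)}")


class AlignmentError(GlandcovError):
    """Species labels of a matrix do not match the expected tip order."""


class ConditioningError(GlandcovError):
    """A covariance matrix is numerically singular or not positive definite."""


class RankDeficientError(GlandcovError):
    """The regression design matrix is rank deficient (collinear predictors)."""


class CompositionError(GlandcovError):
    """Invalid compositional input (negatives, all-zero rows, bad delta)."""


class DegenerateDataError(GlandcovError):
    """A trait block has no variance, so the statistic is undefined."""
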