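"""Exception hierarchy.

All package errors derive from :class:`MorphodisparseError` so callers can
catch the whole family with one clause; the CLI maps them to exit codes.
"""


class MorphodisparseError(Exception):
    """Base class for all errors raised by this package."""


# --- measurement-table validation -------------------------------------------

class MissingColumnError(MorphodisparseError):
    """A required column is absent from the input CSV."""


class EmptyTableError(MorphodisparseError):
    """No usable specimen rows remain after validation."""


class DuplicateSpecimenIdError(MorphodisparseError):
    """Two rows share a specimen id."""


class NonPositiveMeasurementError(MorphodisparseError):
    """A measurement is missing, zero or negative (strict mode)."""


class AmbiguousRegionError(MorphodisparseError):
    """A species is assigned to more than one region."""


# --- trees -------------------------------------------------------------------

class NewickParseError(MorphodisparseError):
    """Malformed Newick input."""


class MissingBranchLengthError(MorphodisparseError):
    """A non-root node lacks a branch length and no default policy is set."""


class UnknownTipError(MorphodisparseError):
    """A requested tip label is not present in the tree."""


class TooFewTipsError(MorphodisparseError):
    """Fewer than two tips would remain after pruning."""


class UnmatchedNamesError(MorphodisparseError):
    """Tree tips and table species cannot be reconciled in strict mode."""

    def __init__(self, unmatched_tips, unmatched_species):
        self.unmatched_tips = list(unmatched_tips)
        self.unmatched_species = list(unmatched_species)
        super().__init__(
            f"unmatched tree tips: {self.unmatched_tips}; "
            f"unmatched table species: {self.unmatched_species}"
        )


class ZeroBranchLengthError(MorphodisparseError):
    """A zero-length branch was found and the epsilon policy is disabled."""


class NameMismatchError(MorphodisparseError):
    """Tree tips and centroid species do not match exactly."""


# --- morphospace / disparity -------------------------------------------------

class DegenerateVariableError(MorphodisparseError):
    """A variable has zero variance and cannot be z-scored."""


class DimensionMismatchError(MorphodisparseError):
    """Coordinate arrays disagree in shape or labelling."""


class SubsetTooSmallError(MorphodisparseError):
    """A neighbor summary needs at least two species."""


class EmptyGroupError(MorphodisparseError):
    """A dispersion group contains no points."""


class InvalidConfigError(MorphodisparseError):
    """A simulation or run configuration fails validation."""


class TargetOutOfRangeError(MorphodisparseError):
    """A tuning target lies outside the attainable range."""
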