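"""Exception hierarchy for pathgc."""


class PathgcError(Exception):
    """Base class for all pathgc errors."""


class InputError(PathgcError, ValueError):
    """Invalid user input: malformed file, out-of-range parameter, bad name."""


class EstimationError(PathgcError, RuntimeError):
    """Least-squares estimation failed (e.g. rank-deficient regressors)."""


class UnstableModelError(PathgcError, ValueError):
    """A VAR process whose companion spectral radius is >= 1 was refused."""


class UndefinedCriterionError(PathgcError, ArithmeticError):
    """Information criterion undefined (small-sample correction blows up)."""


class UndefinedStatisticError(PathgcError, ArithmeticError):
    """A statistic has an empty domain (e.g. sign bias of all-zero input)."""
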