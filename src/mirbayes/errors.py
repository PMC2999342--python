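"""Exception hierarchy shared by all mirbayes modules."""


class MirBayesError(Exception):
    """Base class for all mirbayes errors."""


class InputError(MirBayesError):
    """A referenced input file is missing or unreadable."""


class FormatError(MirBayesError):
    """A file was readable but contained no parseable rows."""


class AlignmentError(MirBayesError):
    """The two evidence sources share no genes."""


class FitError(MirBayesError):
    """A model fit cannot proceed (single-class data, separation, ...)."""


class NumericalError(MirBayesError):
    """A numerical guarantee (e.g. ELBO monotonicity) was violated."""


class EvaluationError(MirBayesError):
    """An evaluation has no overlap between predictions and measurements."""
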