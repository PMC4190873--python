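"""Exception hierarchy shared across the pipeline."""


class SrmQuantError(Exception):
    """Base class for all srmquant errors."""


class InvalidInputError(SrmQuantError, ValueError):
    """An argument violates a documented precondition."""


class StandardFailureError(SrmQuantError):
    """The heavy internal standard is missing or has zero signal.

    The assay is invalid for the affected peptide/sample because the
    light/heavy ratio cannot be formed.
    """


class ReferenceFailureError(SrmQuantError):
    """The reference protein (loading control) ratio is missing or zero."""


class InsufficientBackgroundError(SrmQuantError):
    """Too few background observations to model the detection level."""


class UndefinedScoreError(SrmQuantError):
    """A similarity score is undefined (e.g. an all-zero intensity vector)."""


class AssayDesignWarning(UserWarning):
    """Non-fatal shortfall during assay design (e.g. fewer candidates than
    requested)."""
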