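"""Exception hierarchy shared across the package."""


class EnacDecayError(Exception):
    """Base class for all package-specific errors."""


class AnchorNotFound(EnacDecayError, KeyError):
    """A required flanking anchor gene is not annotated on the sequence."""


class InvalidAnchors(EnacDecayError, ValueError):
    """Anchor annotations overlap or leave no inter-anchor segment."""


class ChainingError(EnacDecayError, ValueError):
    """Exon hits cannot be chained in reference order."""


class NomenclatureError(EnacDecayError, ValueError):
    """More core exons than the standardized labeling scheme allows."""


class EmptySequence(EnacDecayError, ValueError):
    """Sequence is empty or contains no unambiguous bases."""


class FrameError(EnacDecayError, ValueError):
    """Coding sequence length is not a multiple of three."""


class StateMissing(EnacDecayError, KeyError):
    """A tree tip has no presence/loss state assigned."""


class FamilyUnknown(EnacDecayError, KeyError):
    """A species cannot be assigned to a family."""


class EpochMissing(EnacDecayError, ValueError):
    """A required solution/drug epoch is absent from the trace."""


class WindowTooShort(EnacDecayError, ValueError):
    """An epoch is too short for the requested measurement window."""


class FitError(EnacDecayError, RuntimeError):
    """A model fit failed or is singular."""


class FitDiagnosticWarning(UserWarning):
    """Data look inconsistent with the fitted model (e.g. non-monotonic)."""


class InsufficientData(EnacDecayError, ValueError):
    """Too few points for the requested regression."""


class DivisionByZero(EnacDecayError, ZeroDivisionError):
    """Denominator of a ratio statistic is zero."""


class DomainError(EnacDecayError, ValueError):
    """Input values outside the support of the model."""


class SpecError(EnacDecayError, ValueError):
    """A synthetic-data specification is internally inconsistent."""
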