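"""Exception hierarchy shared across the package.

All errors raised by octoneclass derive from :class:`OctError` so callers can
catch package failures with a single except clause while still discriminating
parameter misuse from data problems.
"""


class OctError(Exception):
    """Base class for all octoneclass errors."""


class ParameterError(OctError, ValueError):
    """A configuration or parameter value violates its documented invariant."""


class InputError(OctError, ValueError):
    """An input array/image does not satisfy an operation's precondition."""


class DataError(OctError, ValueError):
    """Training or evaluation data is malformed (bad labels, ragged rows...)."""


class DegenerateInputError(OctError, ValueError):
    """An input is structurally valid but degenerate for the requested
    operation (e.g. an all-zero image, a mask without dermis pixels)."""


class DegeneratePatchError(DegenerateInputError):
    """A pixel group required for feature pooling is empty for this patch.

    Carries the offending group name so dataset builders can decide whether
    to skip the patch or fall back to a coarser group.
    """

    def __init__(self, group: str, message: str | None = None):
        self.group = group
        super().__init__(message or f"pixel group {group!r} is empty for this patch")


class EvaluationError(OctError, ValueError):
    """An evaluation quantity is undefined for the given inputs
    (e.g. ROC AUC with a single class present)."""


class ClassificationError(OctError, RuntimeError):
    """Image-level classification could not produce a score
    (e.g. every patch was degenerate)."""


class StageError(OctError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")
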