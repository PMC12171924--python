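"""Exception hierarchy for fopscan.

All package-raised errors derive from :class:`FopscanError`, so pipeline
callers can distinguish validation failures from genuine bugs.
"""


class FopscanError(Exception):
    """Base class for all fopscan errors."""


class MissingColumnError(FopscanError):
    """A required CSV column is absent; the message names the column."""


class RowValidationError(FopscanError):
    """One or more input rows violated a record invariant.

    Carries the per-row messages so no failure is silently dropped.
    """

    def __init__(self, messages: list[str]):
        self.messages = list(messages)
        preview = "; ".join(self.messages[:5])
        more = "" if len(self.messages) <= 5 else f" (+{len(self.messages) - 5} more)"
        super().__init__(f"{len(self.messages)} invalid row(s): {preview}{more}")


class DuplicateProductCodeError(FopscanError):
    """The label database contains the same product code more than once."""


class UnknownCategoryError(FopscanError):
    """A product's category has no reference amount in the active scheme."""


class UnitMismatchError(FopscanError):
    """g vs mL comparison attempted without a configured density."""


class MissingNutrientError(FopscanError):
    """A nutrient needed for classification is absent under strict policy."""


class InfeasibleMomentsError(FopscanError):
    """Requested mean/SD cannot be realised by a non-negative distribution."""


class PipelineStageError(FopscanError):
    """A pipeline stage failed; the message names the stage."""
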