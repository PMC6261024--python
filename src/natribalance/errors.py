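"""Exception hierarchy for chart validation, prediction and dosing failures."""


class NatribalanceError(Exception):
    """Base class for all package-specific errors."""


class ChartParseError(NatribalanceError):
    """A chart file is structurally unreadable (e.g. a mandatory column is missing)."""


class ChartValidationError(NatribalanceError):
    """One or more chart rows violate a domain invariant.

    ``report_lines`` holds plain-text lines of the form ``"row N: <message>"``.
    """

    def __init__(self, report_lines: list[str]):
        self.report_lines = list(report_lines)
        super().__init__("\n".join(self.report_lines))


class ValidationError(NatribalanceError):
    """A domain object was constructed with invalid field values."""


class DegenerateBalanceError(NatribalanceError):
    """A predictor denominator (body water plus net fluid balance) is not positive."""


class InfeasibleDoseError(NatribalanceError):
    """The dosing equation has no solution (infusate tonicity equals the target)."""


class InsufficientDataError(NatribalanceError):
    """An agreement statistic was requested on fewer than two paired observations."""
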