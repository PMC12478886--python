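"""Package exception types."""


class SchemaError(ValueError):
    """Input file does not match the documented microdata schema."""


class DesignError(ValueError):
    """Design-matrix construction failed (empty groups, missing levels...)."""


class RankDeficiencyError(DesignError):
    """The design matrix is rank deficient or too small to fit."""


class InfeasibleConstraintError(RuntimeError):
    """No grid candidate satisfies the net-age-curve minimum constraint.

    Carries diagnostics: the argmin age group of the candidate net curve at
    the grid endpoints and at zero, to show where the minimum lands instead.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
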