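"""Exception and warning types shared across the package."""


class ValidationError(ValueError):
    """Raised when user-supplied data violates a documented precondition."""


class SchemeError(ValidationError):
    """Raised when a scoring scheme is internally inconsistent."""


class ScoringWarning(UserWarning):
    """Non-fatal issue noticed while scoring (e.g. an endemic species
    recorded in several ecozones, which earns no endemism bonus)."""


class AnalyticsWarning(UserWarning):
    """Non-fatal issue noticed in an assemblage analysis (empty groups,
    low expected counts in a contingency table, and the like)."""
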