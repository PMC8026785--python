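"""Exception types shared across the quantification modules."""


class DomainError(ValueError):
    """An input violates a documented precondition (units, sign, coverage)."""


class InsufficientDataError(DomainError):
    """Too few samples/frames to attempt the requested estimation."""


class FitFailureError(RuntimeError):
    """Nonlinear fit failed to converge after multi-start.

    The best candidate found (if any) is attached as ``best`` so callers can
    inspect how far the optimiser got.
    """

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best
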