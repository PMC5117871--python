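"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A parameter value violates its contract (non-positive SNR, zero size, ...)."""


class InstabilityError(RuntimeError):
    """The active-alignment coefficient 1 - lambda'tau * c/c0 is non-positive
    somewhere on the domain, so the steady-state problem is unstable."""


class FitError(RuntimeError):
    """A least-squares fit failed to converge or the input is degenerate."""


class DegenerateInputError(ValueError):
    """Input carries no usable signal (constant field, empty band, ...)."""
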