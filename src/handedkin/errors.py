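"""Exception hierarchy.

ValidationError maps to CLI exit code 2, NumericalError to exit code 3.
"""


class HandedkinError(Exception):
    """Base class for all package errors."""


class ValidationError(HandedkinError, ValueError):
    """Invalid user input: bad parameters, malformed pedigree or config."""


class ParameterError(ValidationError):
    """Model parameters outside the admissible region (e.g. negative fecundity)."""


class NumericalError(HandedkinError, ArithmeticError):
    """Numerical failure: non-convergence, multiple roots, singular system."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class MultipleRootsError(NumericalError):
    """The selection gradient has several interior roots (model misconfiguration)."""

    def __init__(self, roots):
        super().__init__(f"multiple interior equilibria found: {sorted(roots)}")
        self.roots = sorted(roots)
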