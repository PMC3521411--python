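"""Exception hierarchy shared by all modules.

``ValidationError`` maps to CLI exit code 2, ``ConvergenceError`` to 3.
"""


class MultiwalkError(Exception):
    """Base class for all multiwalk errors."""


class ValidationError(MultiwalkError, ValueError):
    """Malformed input: bad file, violated invariant, out-of-range parameter."""


class ConvergenceError(MultiwalkError, RuntimeError):
    """The power iteration did not reach the requested tolerance."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations
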