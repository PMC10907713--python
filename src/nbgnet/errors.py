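"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Invalid user-supplied parameters or data."""


class SingularMatrixError(ValueError):
    """A matrix that must be inverted is singular (or numerically so)."""


class UnstableTransferError(ValueError):
    """A discrete transfer has spectral radius >= 1 and would diverge."""


class DivergenceError(RuntimeError):
    """A recurrent rollout produced non-finite values."""


class SchemaError(ValueError):
    """An on-disk container does not match the expected schema/version."""
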