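"""Typed exceptions shared across the package."""


class DomainError(ValueError):
    """An argument lies outside the physically admissible domain."""


class LockingError(DomainError):
    """A chain was stretched to (or past) its fully extended length.

    Raised whenever the relative chain stretch lambda_r = lambda_chain/sqrt(N)
    reaches 1, where the inverse Langevin function diverges.  Fitting code
    catches this to reject trial parameter sets instead of crashing.
    """


class HistoryError(ValueError):
    """A softened/pseudo-elastic branch was evaluated beyond its recorded
    deformation history (m > M or W_T > W_max); the virgin equation applies
    there instead."""


class NoResidualError(RuntimeError):
    """The unloading branch has no zero-stress crossing in the search
    bracket, so no residual stretch exists for these parameters."""


class CurveParseError(ValueError):
    """A stress-stretch CSV file could not be parsed; the message carries the
    offending line number."""
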