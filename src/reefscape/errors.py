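"""Exceptions shared across the package."""


class OutOfBoundsError(ValueError):
    """A query point falls outside the spatial/temporal extent of the data."""


class DataGapError(ValueError):
    """Required data are missing at a named location (no-data cells, absent units)."""


class ConvergenceError(RuntimeError):
    """An MCMC fit failed its convergence diagnostics.

    Carries the per-parameter rhat table in ``rhat`` for inspection.
    """

    def __init__(self, message: str, rhat=None):
        super().__init__(message)
        self.rhat = rhat
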