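"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input fails a documented precondition."""


class ScaleOverflowError(ValidationError):
    """Requested more wavelet scales than the raster can support.

    Carries ``max_scales``, the largest feasible number of scales.
    """

    def __init__(self, requested: int, max_scales: int):
        self.requested = requested
        self.max_scales = max_scales
        super().__init__(
            f"n_scales={requested} too large for this raster; "
            f"maximum feasible is {max_scales}"
        )


class PackingError(ValidationError):
    """Nonoverlapping placement (fields or cells) is infeasible.

    ``max_feasible`` is the largest count that could be placed.
    """

    def __init__(self, message: str, max_feasible: int | None = None):
        self.max_feasible = max_feasible
        super().__init__(message)
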