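"""Exception hierarchy.

Every error raised on bad user input derives from :class:`DropquantError`,
so the CLI can map the whole family to exit code 2.
"""


class DropquantError(Exception):
    """Base class for all dropquant errors."""


class ValidationError(DropquantError):
    """An input violated a documented invariant.

    ``field`` names the offending field when the error concerns a
    structured object.
    """

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        if field is not None:
            message = f"{field}: {message}"
        super().__init__(message)


class SaturatedWellError(DropquantError):
    """All droplets in the relevant denominator are positive; lambda = -ln(0) is undefined."""


class UndefinedEstimateError(DropquantError):
    """The requested estimate has an empty denominator (no informative droplets)."""


class InseparableClustersError(DropquantError):
    """Negative and positive amplitude clusters overlap; no threshold can be placed.

    Carries the two 3-sigma spans so the caller can inspect the geometry.
    """

    def __init__(self, channel: str, neg_span: tuple, pos_span: tuple):
        self.channel = channel
        self.neg_span = neg_span
        self.pos_span = pos_span
        super().__init__(
            f"clusters not separable on {channel} channel: "
            f"negative span {neg_span} overlaps positive span {pos_span}"
        )


class ParseError(DropquantError):
    """A file could not be parsed; message includes the line number when known."""


class PlacementError(DropquantError):
    """An oligo sequence could not be located in the target sequence on either strand."""
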