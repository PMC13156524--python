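"""Exception hierarchy shared across the package."""


class TrfaadError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(TrfaadError, ValueError):
    """An argument violated a documented precondition."""


class ZeroVarianceError(TrfaadError, ValueError):
    """A correlation or normalization was requested on a constant signal."""


class FlaggedChannelError(ZeroVarianceError):
    """Normalization failed on specific channels; ``channels`` names them."""

    def __init__(self, channels):
        self.channels = list(channels)
        super().__init__(f"zero-variance channels: {self.channels}")


class FormatError(TrfaadError, ValueError):
    """A serialized container is malformed or missing required groups."""
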