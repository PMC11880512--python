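"""Exception types shared across the package."""


class CedadError(Exception):
    """Base class for all package-specific errors."""


class ExtinctPopulationError(CedadError):
    """Raised when a simulated population has no live cells at harvest."""


class ChannelMappingError(CedadError):
    """Raised when a required cytometry channel cannot be mapped.

    Carries the list of channel names that were available in the source
    file so the caller can build an explicit mapping.
    """

    def __init__(self, message: str, available: list[str] | None = None):
        super().__init__(message)
        self.available = list(available or [])


class ConvergenceError(CedadError):
    """Raised when the generation-mixture EM fails to converge.

    The partially fitted profile is attached as ``.profile`` so callers
    can inspect the last parameter state.
    """

    def __init__(self, message: str, profile=None):
        super().__init__(message)
        self.profile = profile
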