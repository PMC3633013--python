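"""Exception hierarchy."""


class BeauwalkError(Exception):
    """Base class for all package-specific errors."""


class DataError(BeauwalkError):
    """Malformed or inconsistent track / curve data."""


class FitError(BeauwalkError):
    """A parameter fit failed to converge."""
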