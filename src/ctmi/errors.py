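"""Exception types shared across the package."""


class CTMIError(Exception):
    """Base class for all package-specific errors."""


class InvalidWindowError(CTMIError, ValueError):
    """A window size is incompatible with the series it is applied to."""


class EmptySampleError(CTMIError, ValueError):
    """No joint observation satisfies the requested lag/window constraints."""


class SampleSizeError(CTMIError, ValueError):
    """The sample is too small for the requested neighbor count."""


class EstimationInfeasibleError(CTMIError, ValueError):
    """No point of the lag/window search grid yields a usable joint sample."""
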