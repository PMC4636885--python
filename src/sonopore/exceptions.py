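"""Exception types shared across the package."""


class SonoporeError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(SonoporeError, ValueError):
    """A simulation or analysis parameter is outside its supported range."""


class DegenerateDataError(SonoporeError, ValueError):
    """Input data are degenerate for the requested computation.

    Raised for e.g. constant images (no histogram split exists), masks with
    fewer than two grid points, empty backgrounds, or zero baseline counts.
    """


class UnsupportedDesignError(SonoporeError, ValueError):
    """The experimental design does not match what the analysis supports."""


class CapacityError(SonoporeError, RuntimeError):
    """A rejection-sampling generator could not place all requested objects."""
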