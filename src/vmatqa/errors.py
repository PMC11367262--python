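"""Exception hierarchy shared across the package."""


class VmatQAError(Exception):
    """Base class for all package errors."""


class ValidationError(VmatQAError, ValueError):
    """An object violates a domain invariant (e.g. non-monotone meterset)."""


class UnsupportedBeamError(VmatQAError):
    """A beam cannot be interpreted as a dynamic VMAT arc."""


class ClosedApertureError(VmatQAError):
    """An arc exposes no open aperture, so aperture metrics are undefined."""


class GammaInputError(VmatQAError, ValueError):
    """Dose grids cannot be compared (disjoint, or nothing above cut-off)."""
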