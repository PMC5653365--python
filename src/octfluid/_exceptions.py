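"""Exception hierarchy for octfluid."""


class OctFluidError(Exception):
    """Base class for all octfluid errors."""


class InvalidParameterError(OctFluidError, ValueError):
    """An algorithm parameter is out of its valid range."""


class InvalidInputError(OctFluidError, ValueError):
    """An input array/curve violates a precondition (shape, emptiness, ...)."""


class DegenerateImageError(InvalidInputError):
    """The image carries no usable contrast (e.g. constant intensity), so the
    neutrosophic normalization is undefined and no meaningful segmentation exists."""


class InvalidSpecError(OctFluidError, ValueError):
    """A phantom specification is geometrically inconsistent."""
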