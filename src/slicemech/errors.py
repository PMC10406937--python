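"""Exception hierarchy used across the package."""


class SliceMechError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SliceMechError, ValueError):
    """A physical parameter violates its invariant (e.g. non-positive modulus)."""


class DomainError(SliceMechError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class InvalidInputError(SliceMechError, ValueError):
    """Malformed or empty data passed to an analysis routine."""


class MalformedCurveError(InvalidInputError):
    """A force-distance recording does not have the expected approach/retract shape."""


class NoContactError(SliceMechError):
    """No contact point improves on the flat (no-contact) model of an approach segment."""


class SegmentationError(SliceMechError):
    """Image segmentation failed to find a slice-sized foreground component."""


class ConfigurationError(SliceMechError, ValueError):
    """A run configuration is inconsistent or incomplete."""
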