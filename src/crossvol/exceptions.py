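"""Exception hierarchy for crossvol."""


class CrossvolError(Exception):
    """Base class for all crossvol errors."""


class ValidationError(CrossvolError):
    """Input data violate a structural requirement (malformed slab,
    mismatched boundaries, void outside the body, ...)."""


class DegenerateSectionError(CrossvolError):
    """A shape ratio was requested at a section with zero identity segment.

    Shape ratios divide by the identity segment, so they are undefined at a
    cone apex; terminal slabs must use cone mode instead."""


class MeasurementError(CrossvolError):
    """A silhouette/section measurement could not be taken
    (empty mask, station outside the image, multiple components, ...)."""
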