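"""Exception hierarchy for oirquant.

Every anticipated failure mode raises a subclass of :class:`OirQuantError`
so the CLI can surface a single diagnostic message instead of a traceback.
"""


class OirQuantError(Exception):
    """Base class for all oirquant errors."""


class FormatError(OirQuantError):
    """Unsupported image format, bit depth or channel layout."""


class EmptySelectionError(OirQuantError):
    """A mask or ROI selected zero pixels."""


class DegenerateHistogramError(OirQuantError):
    """Histogram has fewer than two occupied bins; no threshold exists."""


class EmptyRetinaError(OirQuantError):
    """Retina segmentation produced no foreground."""


class MaskHierarchyError(OirQuantError):
    """Mask nesting invariant (neovascular ⊆ vascular ⊆ retina) violated."""


class NormalizationError(OirQuantError):
    """Reference spots integrate to zero; membrane cannot be normalized."""


class UndefinedLacunarityError(OirQuantError):
    """Lacunarity requested on an empty mask."""
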