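"""Exception hierarchy shared across the pipeline."""


class NemaQuantError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(NemaQuantError, ValueError):
    """A caller supplied an argument outside the documented domain."""


class CoverageError(NemaQuantError, ValueError):
    """A grid does not cover the object it is asked to rasterize/sample."""


class AlignmentError(NemaQuantError, ValueError):
    """Two gridded objects do not share the same grid."""


class GeometryError(NemaQuantError, RuntimeError):
    """A geometric construction (ROI placement, phantom layout) failed."""


class SegmentationInfeasibleError(NemaQuantError, RuntimeError):
    """Segmentation cannot produce a meaningful VOI.

    This is a first-class result state for batch drivers: sweeps catch it
    and record an infeasible row instead of aborting.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason
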