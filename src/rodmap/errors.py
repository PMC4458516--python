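"""Exception types shared across the pipeline stages."""


class RodmapError(Exception):
    """Base class for all rodmap errors."""


class FormatError(RodmapError):
    """Input image or table does not have the expected structure."""


class ShapeError(RodmapError):
    """A segmented object is too round/degenerate for medial-axis analysis."""


class PlacementError(RodmapError):
    """Synthetic cells could not all be placed in the requested field."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could only place {placed} of {requested} cells without overlap; "
            "enlarge the field or reduce n"
        )


class CalibrationError(RodmapError):
    """Too few reference cells to calibrate a percentile threshold."""


class StateError(RodmapError):
    """An operation was called before a prerequisite step (e.g. missing axis)."""


class ConsistencyError(RodmapError):
    """Cross-referenced records disagree (e.g. profile cell_id not in table)."""
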