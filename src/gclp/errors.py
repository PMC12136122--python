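"""Exception hierarchy for the gclp pipeline."""


class GclpError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(GclpError):
    """A configuration or grid produces impossible geometry (overlapping layers,
    degenerate polar grid, mismatched map shapes)."""


class SegmentationError(GclpError):
    """Retinal surface set violates ordering or bounds invariants.

    Carries the offending A-line indices in ``alines`` as an (n, 2) array of
    (x, y) index pairs.
    """

    def __init__(self, message, alines=None):
        super().__init__(message)
        self.alines = alines


class NoWatershedError(GclpError):
    """The fitted vessel-density depth profile has no interior local minimum
    posterior to the peak, so no GCLP/ICP watershed can be located."""


class NoWatershedTruthError(GclpError):
    """The planted plexus configuration yields no interior minimum of axial
    vessel density between the GCLP and the ICP, so the phantom has no
    ground-truth watershed."""


class MissingDataError(GclpError):
    """A regional statistic was requested over a region that is empty after
    low-signal exclusion."""
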