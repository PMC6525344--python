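"""Exception hierarchy for the ONL shape-analysis pipeline."""


class OnlShapeError(Exception):
    """Base class for all package errors."""


class FormatError(OnlShapeError):
    """A file does not conform to the expected on-disk format."""


class SegmentationCrossingError(OnlShapeError):
    """RPE surface lies above the ONL/OPL boundary somewhere.

    Anatomically the RPE is the deepest surface, so ``rpe_depth >= onl_depth``
    must hold at every A-scan. The first offending (b-scan, a-scan) cell is
    reported.
    """

    def __init__(self, row: int, col: int, onl: float, rpe: float):
        self.row, self.col = row, col
        super().__init__(
            f"segmentation surfaces cross at cell ({row}, {col}): "
            f"rpe={rpe:.3f} < onl={onl:.3f}"
        )


class ParameterError(OnlShapeError, ValueError):
    """An argument is outside its documented domain."""


class GeometryError(OnlShapeError):
    """A contour or region is degenerate (zero area, collinear, ...)."""


class NoContourError(OnlShapeError):
    """The requested superlevel set is empty; no iso-contour exists."""


class SelectionFailureError(OnlShapeError):
    """No height level satisfies the ONL-Base admissibility criteria.

    Carries the per-level diagnostics so QC reports can show which
    criterion failed where.
    """

    def __init__(self, message: str, diagnostics=None):
        self.diagnostics = diagnostics or []
        super().__init__(message)


class StatisticsError(OnlShapeError):
    """A statistic is undefined for the given sample (constant vector, n too small)."""
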