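"""Construction of the 512x512 ONL height image and its reference plane.

The ONL is measured, per A-scan, as the axial distance from the ONL/OPL
boundary down to the RPE line. Stacking these distances over the 49 B-scans
and linearly interpolating along the slow (B-scan) axis to 512 rows yields
a square height image ("HI") whose value at each lateral position is the
local ONL thickness in axial pixels; multiplying by the axial scale
(3.87 um per pixel by default) gives micrometres.

The *reference plane* is the height level at the mode of the HI histogram —
the background thickness of the ONL away from the foveal bump — and anchors
the upward search for the ONL-Base contour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import interp1d

from .errors import ParameterError, SegmentationCrossingError
from .surface_io import SurfaceStack

logger = logging.getLogger(__name__)

AXIAL_SCALE_UM = 3.87  # um per axial pixel
LATERAL_EXTENT_MM = 6.7  # 20-degree field
HI_SIZE = 512


@dataclass
class HeightImage:
    """Square ONL thickness map with axial/lateral scale metadata."""

    heights_px: np.ndarray
    axial_scale_um: float = AXIAL_SCALE_UM
    lateral_extent_mm: float = LATERAL_EXTENT_MM
    laterality: str = "OS"
    subject_id: str = "anon"

    def __post_init__(self):
        self.heights_px = np.asarray(self.heights_px, dtype=float)
        if self.heights_px.ndim != 2:
            raise ParameterError("heights_px must be 2-D")
        if not np.all(np.isfinite(self.heights_px)):
            raise ParameterError("heights_px contains non-finite values")
        if self.heights_px.min() < 0:
            raise ParameterError("heights must be non-negative")

    @property
    def heights_um(self) -> np.ndarray:
        """Micrometre view; exact elementwise scaling of the pixel view."""
        return self.heights_px * self.axial_scale_um

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights_px.shape


@dataclass
class ReferenceLevel:
    """Mode of the height histogram: the baseline section of the ONL."""

    level_px: float
    bin_width_px: float
    bin_edges: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)

    def level_um(self, axial_scale_um: float = AXIAL_SCALE_UM) -> float:
        return self.level_px * axial_scale_um


def thickness_grid(stack: SurfaceStack) -> np.ndarray:
    """Per-A-scan ONL thickness (rpe - onl) in axial pixels, shape 49x512."""
    diff = stack.rpe_depth - stack.onl_depth
    if (diff < 0).any():
        r, c = np.argwhere(diff < 0)[0]
        raise SegmentationCrossingError(
            int(r), int(c), float(stack.onl_depth[r, c]), float(stack.rpe_depth[r, c])
        )
    return diff


def interpolate_rows(grid: np.ndarray, target_rows: int = HI_SIZE) -> np.ndarray:
    """Resample the slow (B-scan) axis to ``target_rows`` rows.

    Input row ``i`` maps to output position ``i * (target_rows - 1) / (n_in - 1)``
    so the first and last B-scans are reproduced exactly; intermediate output
    rows are linear interpolations of the two bracketing input rows.
    """
    grid = np.asarray(grid, dtype=float)
    n_in = grid.shape[0]
    if n_in < 2:
        raise ParameterError("need at least 2 input rows to interpolate")
    if target_rows < n_in:
        raise ParameterError(
            f"target_rows={target_rows} smaller than input row count {n_in}"
        )
    src_pos = np.linspace(0.0, target_rows - 1.0, n_in)
    f = interp1d(src_pos, grid, axis=0, kind="linear", assume_sorted=True)
    return f(np.arange(target_rows, dtype=float))


def build_height_image(
    stack: SurfaceStack,
    axial_scale_um: float = AXIAL_SCALE_UM,
    size: int = HI_SIZE,
) -> HeightImage:
    """Thickness grid -> row interpolation -> :class:`HeightImage`.

    Interpolation runs on pixel heights; the micrometre view is a pure
    scalar multiply afterwards.
    """
    hp = interpolate_rows(thickness_grid(stack), target_rows=size)
    return HeightImage(
        heights_px=hp,
        axial_scale_um=axial_scale_um,
        laterality=stack.laterality,
        subject_id=stack.subject_id,
    )


def reference_level(
    hi: HeightImage,
    bin_width_px: float = 1.0,
    include_zero: bool = True,
) -> ReferenceLevel:
    """Histogram mode of the height image.

    Bins are centred on integer multiples of ``bin_width_px`` (edges at
    ``k*bw - bw/2``), matching the native axial quantization, so a constant
    integer-height image returns that height exactly. Ties between equal
    maximal bins break toward the lower bin.
    """
    if bin_width_px <= 0:
        raise ParameterError("bin_width_px must be positive")
    h = hi.heights_px.ravel()
    if not include_zero:
        h = h[h > 0]
    if h.size == 0 or h.max() == 0:
        logger.warning("height image is all-zero; reference level set to 0")
        edges = np.array([-bin_width_px / 2, bin_width_px / 2])
        return ReferenceLevel(0.0, bin_width_px, edges, np.array([h.size]))
    bw = bin_width_px
    n_bins = int(np.floor(h.max() / bw + 0.5)) + 1
    edges = (np.arange(n_bins + 1) - 0.5) * bw
    counts, _ = np.histogram(h, bins=edges)
    k = int(np.argmax(counts))  # argmax returns the first (lowest) maximal bin
    return ReferenceLevel(level_px=k * bw, bin_width_px=bw, bin_edges=edges, counts=counts)


def onl_height_summary(
    hi: HeightImage,
    ref: ReferenceLevel | None = None,
    mode: str = "reference_level",
) -> float:
    """Per-subject "ONL height" statistic in micrometres.

    ``reference_level`` (default) reports the baseline thickness of the ONL
    (the histogram mode); ``mean`` and ``max`` report the corresponding
    statistics of the full map.
    """
    if mode == "reference_level":
        if ref is None:
            ref = reference_level(hi)
        return ref.level_px * hi.axial_scale_um
    if mode == "mean":
        return float(hi.heights_um.mean())
    if mode == "max":
        return float(hi.heights_um.max())
    raise ParameterError(f"unknown ONL-height mode {mode!r}")


def write_height_grid(hi: HeightImage, path) -> str:
    """Export the pixel-height grid as a tab-delimited text raster."""
    np.savetxt(path, hi.heights_px, fmt="%.3f", delimiter="\t")
    return str(path)


def write_height_png(hi: HeightImage, path) -> str:
    """Export as 16-bit grayscale PNG/TIFF (value = height in axial pixels)."""
    import imageio.v3 as iio

    img = np.clip(np.round(hi.heights_px), 0, 65535).astype(np.uint16)
    iio.imwrite(path, img)
    return str(path)
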