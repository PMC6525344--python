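"""Reading and writing segmentation-surface stacks and subject metadata.

A *surface stack* holds, for one eye, the axial (depth) position of two
segmented surfaces on every A-scan of a volumetric OCT acquisition: the
ONL/OPL boundary and the RPE line. The macular cube is 49 B-scans of
512 A-scans over a 20-degree (6.7 x 6.7 mm) field, 400 axial pixels deep,
so each surface is a 49 x 512 grid of depths in axial pixels. Depths may
be fractional (segmentation is sub-pixel after manual correction).

The on-disk format is a small self-describing text file (``.surf.txt``)::

    # onlshape surface stack v1
    #subject s01
    #laterality OS
    #shape 49 512
    #axial_range 400
    # row 0 = superior-most B-scan; column 0 = leftmost A-scan of the
    # displayed image; depths in axial pixels from the top of the cube.
    ONL:
    <49 rows x 512 tab-separated depths, 3 decimals>
    RPE:
    <49 rows x 512 tab-separated depths, 3 decimals>

The writer emits tabs; the reader accepts any whitespace. Depth grids can
also be imported from a pair of 16-bit grayscale PNG/TIFF rasters
(pixel value = depth in axial pixels).

Subject metadata is a CSV table with header
``subject_id,group,laterality,mh,mv,logmar_va`` where ``mh``/``mv`` are
MCHART metamorphopsia scores in viewing-angle degrees (0 = no detected
distortion, chart range 0.2-2.0).
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, SegmentationCrossingError

logger = logging.getLogger(__name__)

LATERALITIES = ("OD", "OS")
GROUPS = ("ERM", "control")

MCHART_MAX = 2.0  # largest dot-gap viewing angle on the chart, degrees

SUBJECT_COLUMNS = ["subject_id", "group", "laterality", "mh", "mv", "logmar_va"]


@dataclass
class SurfaceStack:
    """Paired ONL/OPL-boundary and RPE depth grids for one eye.

    Rows index B-scans (superior to inferior), columns index A-scans
    (left to right on the displayed image); values are axial positions in
    pixels from the top of the OCT cube, increasing with depth.
    """

    onl_depth: np.ndarray
    rpe_depth: np.ndarray
    subject_id: str = "anon"
    laterality: str = "OS"
    axial_range_px: int = 400

    def __post_init__(self):
        self.onl_depth = np.asarray(self.onl_depth, dtype=float)
        self.rpe_depth = np.asarray(self.rpe_depth, dtype=float)
        self.validate()

    @property
    def n_bscans(self) -> int:
        return self.onl_depth.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.onl_depth.shape[1]

    def validate(self) -> None:
        if self.laterality not in LATERALITIES:
            raise ParameterError(f"laterality must be one of {LATERALITIES}, got {self.laterality!r}")
        if self.onl_depth.ndim != 2 or self.onl_depth.shape != self.rpe_depth.shape:
            raise FormatError(
                f"surface grids must be 2-D with identical shapes, got "
                f"{self.onl_depth.shape} and {self.rpe_depth.shape}"
            )
        for name, grid in (("onl", self.onl_depth), ("rpe", self.rpe_depth)):
            if not np.all(np.isfinite(grid)):
                raise FormatError(f"{name} depth grid contains non-finite values")
            if grid.min() < 0 or grid.max() >= self.axial_range_px:
                raise FormatError(
                    f"{name} depths must lie in [0, {self.axial_range_px}), "
                    f"found range [{grid.min():.3f}, {grid.max():.3f}]"
                )
        crossing = self.rpe_depth < self.onl_depth
        if crossing.any():
            r, c = np.argwhere(crossing)[0]
            raise SegmentationCrossingError(
                int(r), int(c), float(self.onl_depth[r, c]), float(self.rpe_depth[r, c])
            )


@dataclass
class SubjectMeta:
    """Per-eye clinical metadata: group label, laterality, MCHART scores, acuity."""

    subject_id: str
    group: str
    laterality: str
    mh: float
    mv: float
    logmar_va: float = float("nan")

    def __post_init__(self):
        if self.group not in GROUPS:
            raise FormatError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.laterality not in LATERALITIES:
            raise FormatError(f"laterality must be one of {LATERALITIES}, got {self.laterality!r}")
        for name, score in (("mh", self.mh), ("mv", self.mv)):
            if not (0.0 <= score <= MCHART_MAX):
                raise ParameterError(
                    f"{name}={score} outside the MCHART score range [0, {MCHART_MAX}]"
                )


def write_surface_stack(stack: SurfaceStack, path: str | os.PathLike) -> str:
    """Write ``stack`` to ``path`` in the ``.surf.txt`` text format.

    Output is deterministic: fixed field order, 3-decimal depths, tab
    delimiters, so identical stacks produce byte-identical files.
    """
    stack.validate()
    buf = io.StringIO()
    buf.write("# onlshape surface stack v1\n")
    buf.write(f"#subject {stack.subject_id}\n")
    buf.write(f"#laterality {stack.laterality}\n")
    buf.write(f"#shape {stack.n_bscans} {stack.n_ascans}\n")
    buf.write(f"#axial_range {stack.axial_range_px}\n")
    buf.write("# row 0 = superior-most B-scan; column 0 = leftmost A-scan; "
              "depths in axial pixels\n")
    for label, grid in (("ONL", stack.onl_depth), ("RPE", stack.rpe_depth)):
        buf.write(f"{label}:\n")
        for row in grid:
            buf.write("\t".join(f"{v:.3f}" for v in row))
            buf.write("\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
    return str(path)


def read_surface_stack(path: str | os.PathLike) -> SurfaceStack:
    """Read a ``.surf.txt`` file and return a validated :class:`SurfaceStack`."""
    header: dict[str, str] = {}
    blocks: dict[str, list[list[float]]] = {}
    current: list[list[float]] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split(None, 1)
                if parts and parts[0] in ("subject", "laterality", "shape", "axial_range"):
                    header[parts[0]] = parts[1].strip() if len(parts) > 1 else ""
                continue
            if line.endswith(":"):
                name = line[:-1].upper()
                if name not in ("ONL", "RPE"):
                    raise FormatError(f"{path}:{lineno}: unknown block {name!r}")
                current = blocks.setdefault(name, [])
                continue
            if current is None:
                raise FormatError(f"{path}:{lineno}: data before any ONL:/RPE: block")
            try:
                current.append([float(v) for v in line.replace(",", "\t").split()])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric depth value") from exc

    for key in ("subject", "laterality", "shape", "axial_range"):
        if key not in header:
            raise FormatError(f"{path}: missing required header line '#{key}'")
    try:
        rows, cols = (int(v) for v in header["shape"].split())
        axial_range = int(header["axial_range"])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed #shape or #axial_range header") from exc

    grids = {}
    for name in ("ONL", "RPE"):
        if name not in blocks:
            raise FormatError(f"{path}: missing {name}: block")
        grid = np.array(blocks[name], dtype=float)
        if grid.shape != (rows, cols):
            raise FormatError(
                f"{path}: {name} block has shape {grid.shape}, header declares {(rows, cols)}"
            )
        grids[name] = grid

    return SurfaceStack(
        onl_depth=grids["ONL"],
        rpe_depth=grids["RPE"],
        subject_id=header["subject"],
        laterality=header["laterality"],
        axial_range_px=axial_range,
    )


def read_surface_images(
    onl_path: str | os.PathLike,
    rpe_path: str | os.PathLike,
    subject_id: str = "anon",
    laterality: str = "OS",
    axial_range_px: int = 400,
) -> SurfaceStack:
    """Import a stack from two single-channel rasters (16-bit PNG or TIFF).

    Pixel value = depth in axial pixels; integer quantization is accepted
    as-is.
    """
    import imageio.v3 as iio

    grids = []
    for p in (onl_path, rpe_path):
        img = np.asarray(iio.imread(p))
        if img.ndim != 2:
            raise FormatError(f"{p}: expected a single-channel image, got shape {img.shape}")
        grids.append(img.astype(float))
    return SurfaceStack(grids[0], grids[1], subject_id=subject_id,
                        laterality=laterality, axial_range_px=axial_range_px)


def read_subject_table(path: str | os.PathLike) -> list[SubjectMeta]:
    """Read subject metadata from CSV (or TSV); returns one record per row."""
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: could not parse subject table: {exc}") from exc
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: subject table missing columns {missing}")
    if df.empty:
        logger.warning("subject table %s is empty", path)
        return []
    dupes = df["subject_id"][df["subject_id"].duplicated()]
    if not dupes.empty:
        raise FormatError(f"{path}: duplicate subject_id values: {sorted(set(dupes))}")
    records = []
    for _, row in df.iterrows():
        records.append(SubjectMeta(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            laterality=str(row["laterality"]),
            mh=float(row["mh"]),
            mv=float(row["mv"]),
            logmar_va=float(row["logmar_va"]),
        ))
    return records


def write_subject_table(records: Sequence[SubjectMeta], path: str | os.PathLike) -> str:
    """Write subject metadata as CSV with the canonical column order."""
    df = pd.DataFrame(
        [{
            "subject_id": m.subject_id, "group": m.group, "laterality": m.laterality,
            "mh": m.mh, "mv": m.mv, "logmar_va": m.logmar_va,
        } for m in records],
        columns=SUBJECT_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.3f")
    return str(path)
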