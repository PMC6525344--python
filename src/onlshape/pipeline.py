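"""End-to-end orchestration: per-subject analysis and cohort runs.

``analyze_subject`` composes the full measurement chain for one eye:
height-image construction, reference plane, ONL-B level search, moment
ellipse fit, laterality-adjusted angle and the three shape parameters.
``run_cohort`` maps it over a directory of surface files plus a subject
table, excludes (and reports) eyes whose ONL-B selection fails, and writes
the per-subject results, the two cohort tables and a run report. All steps
are deterministic given inputs and configuration, so reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort_stats import (
    SubjectRecord,
    table1_summary,
    table2_correlations,
)
from .errors import FormatError, ParameterError, SelectionFailureError, StatisticsError
from .ellipse_fit import shape_params
from .height_map import build_height_image, onl_height_summary, reference_level
from .onlb import select_onlb
from .surface_io import SubjectMeta, SurfaceStack, read_subject_table, read_surface_stack

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "subject_id", "group", "laterality", "mh", "mv", "logmar_va", "mh_mv",
    "level_um", "onl_height_um", "axis_deg", "circularity",
    "area_ratio", "axis_ratio", "excluded", "exclusion_reason",
]


@dataclass
class RunConfig:
    """All tunable constants of the pipeline, serialized into every report."""

    axial_scale_um: float = 3.87
    bin_width_px: float = 1.0
    onl_height_mode: str = "reference_level"
    concave_area_max_px2: float = 20_000.0
    hull_ratio_max: float = 1.2
    restore_ratio_min: float = 0.95
    n_harmonics: int = 5
    point_counts: tuple[int, ...] = (100, 50, 25)
    level_step_px: float = 1.0
    max_level_frac: float = 0.95
    axis_window_deg: float = 10.0
    t_test: str = "welch"
    mirror_od: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["point_counts"] = list(d["point_counts"])
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML (.yml/.yaml) or TOML (.toml)."""
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(path.read_text()) or {}
        elif path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            raise ParameterError(f"unsupported config format {path.suffix!r}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "point_counts" in data:
            data["point_counts"] = tuple(int(v) for v in data["point_counts"])
        return cls(**data)


def analyze_subject(stack: SurfaceStack, meta: SubjectMeta,
                    cfg: RunConfig | None = None) -> SubjectRecord:
    """Run the full measurement chain for one eye.

    Raises :class:`SelectionFailureError` when no admissible ONL-B level
    exists; cohort drivers translate that into an exclusion.
    """
    cfg = cfg or RunConfig()
    hi = build_height_image(stack, axial_scale_um=cfg.axial_scale_um)
    ref = reference_level(hi, bin_width_px=cfg.bin_width_px)
    result = select_onlb(
        hi, ref,
        step_px=cfg.level_step_px,
        max_level_frac=cfg.max_level_frac,
        concave_area_max=cfg.concave_area_max_px2,
        hull_ratio_max=cfg.hull_ratio_max,
        restore_min=cfg.restore_ratio_min,
        n_harmonics=cfg.n_harmonics,
        point_counts=cfg.point_counts,
    )
    laterality = meta.laterality if cfg.mirror_od else "OS"
    shape, _fit = shape_params(result.contour, laterality, n_harmonics=cfg.n_harmonics)
    return SubjectRecord(
        meta=meta,
        shape=shape,
        onl_height_um=onl_height_summary(hi, ref, mode=cfg.onl_height_mode),
        level_um=result.level_um,
    )


def records_to_frame(records, exclusions=None) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.meta.subject_id, "group": r.meta.group,
            "laterality": r.meta.laterality, "mh": r.meta.mh, "mv": r.meta.mv,
            "logmar_va": r.meta.logmar_va, "mh_mv": r.mh_mv,
            "level_um": r.level_um, "onl_height_um": r.onl_height_um,
            "axis_deg": r.shape.axis_deg, "circularity": r.shape.circularity,
            "area_ratio": r.shape.area_ratio, "axis_ratio": r.shape.axis_ratio,
            "excluded": False, "exclusion_reason": "",
        })
    for meta, reason in (exclusions or []):
        rows.append({
            "subject_id": meta.subject_id, "group": meta.group,
            "laterality": meta.laterality, "mh": meta.mh, "mv": meta.mv,
            "logmar_va": meta.logmar_va, "mh_mv": None,
            "level_um": None, "onl_height_um": None, "axis_deg": None,
            "circularity": None, "area_ratio": None, "axis_ratio": None,
            "excluded": True, "exclusion_reason": reason,
        })
    df = pd.DataFrame(rows)
    return df.reindex(columns=[c for c in RESULT_COLUMNS if c in df.columns])


def frame_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    """Rebuild subject records from a results table (excluded rows dropped)."""
    from .ellipse_fit import ShapeParams

    records = []
    for _, row in df.iterrows():
        if row.get("excluded", False):
            continue
        meta = SubjectMeta(
            subject_id=str(row["subject_id"]), group=str(row["group"]),
            laterality=str(row["laterality"]), mh=float(row["mh"]),
            mv=float(row["mv"]), logmar_va=float(row["logmar_va"]),
        )
        shape = ShapeParams(
            circularity=float(row["circularity"]),
            area_ratio=float(row["area_ratio"]),
            axis_ratio=float(row["axis_ratio"]),
            axis_deg=float(row["axis_deg"]),
        )
        records.append(SubjectRecord(
            meta=meta, shape=shape,
            onl_height_um=float(row["onl_height_um"]),
            level_um=float(row["level_um"]),
        ))
    return records


def write_tables(records, out_dir: Path, cfg: RunConfig) -> dict:
    """Write table1.csv / table2.csv; returns a small summary dict."""
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    groups = {r.meta.group for r in records}
    if {"ERM", "control"} <= groups or len(records) >= 2:
        try:
            t1 = table1_summary(records, t_variant=cfg.t_test)
            t1.to_csv(out_dir / "table1.csv", index=False, float_format="%.6f")
            written["table1"] = str(out_dir / "table1.csv")
        except StatisticsError as exc:
            logger.warning("table1 skipped: %s", exc)
    try:
        t2 = table2_correlations(records, axis_window_deg=cfg.axis_window_deg)
        t2.to_csv(out_dir / "table2.csv", index=False, float_format="%.6f")
        written["table2"] = str(out_dir / "table2.csv")
    except StatisticsError as exc:
        logger.warning("table2 skipped: %s", exc)
    return written


def run_cohort(input_dir, cfg: RunConfig | None = None, out_dir=None) -> pd.DataFrame:
    """Analyze every subject in ``input_dir`` and write the result bundle.

    Expects ``subjects.csv`` plus one ``<subject_id>.surf.txt`` per row.
    Subjects whose ONL-B selection fails are excluded with a recorded
    reason, mirroring clinical QC exclusions, not silently dropped.
    """
    cfg = cfg or RunConfig()
    input_dir = Path(input_dir)
    table_path = input_dir / "subjects.csv"
    if not table_path.exists():
        raise FormatError(f"missing subject table: {table_path}")
    metas = read_subject_table(table_path)
    records, exclusions = [], []
    for meta in metas:
        surf = input_dir / f"{meta.subject_id}.surf.txt"
        if not surf.exists():
            exclusions.append((meta, f"missing surface file {surf.name}"))
            continue
        stack = read_surface_stack(surf)
        try:
            records.append(analyze_subject(stack, meta, cfg))
        except SelectionFailureError as exc:
            logger.warning("subject %s excluded: %s", meta.subject_id, exc)
            exclusions.append((meta, "ONL-B selection failed"))
    if not records:
        raise SelectionFailureError("no analyzable subjects in cohort")

    df = records_to_frame(records, exclusions)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "results.csv", index=False, float_format="%.6f")
        written = write_tables(records, out_dir, cfg)
        report = {
            "onlshape_version": __version__,
            "config": cfg.to_dict(),
            "n_input": len(metas),
            "n_analyzed": len(records),
            "excluded": [{"subject_id": m.subject_id, "reason": r}
                         for m, r in exclusions],
            "outputs": {"results": str(out_dir / "results.csv"), **written},
        }
        (out_dir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return df


def render_overlay(hi, result, fit, path) -> str:
    """QC figure: height map with the ONL-B contour and fitted ellipse."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(hi.heights_px, cmap="viridis", origin="upper")
    v = result.contour.closed_vertices()
    ax.plot(v[:, 0], v[:, 1], color="magenta", lw=1.2, label="ONL-B")
    t = np.linspace(0, 2 * np.pi, 200)
    a2, b2 = fit.major_axis_a / 2, fit.minor_axis_b / 2
    th = np.radians(-fit.theta_deg)  # back to image (y-down) frame
    ex = fit.center_O[0] + a2 * np.cos(t) * np.cos(th) - b2 * np.sin(t) * np.sin(th)
    ey = fit.center_O[1] + a2 * np.cos(t) * np.sin(th) + b2 * np.sin(t) * np.cos(th)
    ax.plot(ex, ey, color="white", lw=1.0, ls="--", label="moment ellipse")
    ax.legend(loc="lower right")
    ax.set_title(f"{hi.subject_id} ONL-B at {result.level_um:.1f} um")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
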