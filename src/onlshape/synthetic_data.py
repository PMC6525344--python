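"""Synthetic OCT surface stacks and cohorts with known ground truth.

No patient imaging underlies the test suite, so every pipeline stage is
exercised on simulated eyes. The generator emulates the acquisition
geometry of a 20-degree (6.7 x 6.7 mm) macular cube — 49 B-scans of 512
A-scans, 400 axial pixels at 3.87 um — and places an elliptical foveal
bump of ONL thickening on a flat background:

    h(x, y) = base + peak * exp(-rho_eff^2 / 2)

where ``rho_eff`` is the elliptical radius in the frame rotated to the
true axis angle, optionally divided by a radial ripple factor
``1 + ripple_amp * cos(ripple_lobes * phi)`` so that every level set is the
same rippled ellipse up to scale. With zero ripple every level set is an
exact ellipse with axis ratio ``sigma_major / sigma_minor`` at the true
angle, making recovery targets independent of the selected ONL-B level.

Surface noise emulates segmentation jitter as additive Gaussian noise per
grid cell (iid by default). An optional lateral correlation length turns it
into a smooth random field; correlated noise displaces the traced contour
in coherent lobes and degrades angle recovery markedly, which is worth
knowing when modelling systematic segmentation error.

Cohorts draw per-subject bump parameters from group-level distributions and
generate MCHART scores whose ratio MH/MV is linked to the ground-truth
deformation with a controllable correlation, then quantized to the 0.1-step
chart grid (scores below the 0.2-degree chart minimum record as 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .ellipse_fit import (
    area_ratio,
    axis_ratio,
    circularity,
    fit_ellipse_moments,
    region_moments,
    wrap_angle_deg,
)
from .errors import ParameterError
from .height_map import AXIAL_SCALE_UM, HI_SIZE
from .onlb import Contour
from .surface_io import SubjectMeta, SurfaceStack

N_BSCANS = 49
N_ASCANS = 512
AXIAL_RANGE_PX = 400


@dataclass
class BumpModel:
    """Parameters of one synthetic eye's ONL thickness map."""

    base_height_px: float = 14.0
    peak_height_px: float = 36.0
    sigma_major_px: float = 70.0
    sigma_minor_px: float = 50.0
    theta_true_deg: float = 0.0  # major-axis angle in the left-eye fundus frame
    ripple_amp: float = 0.0
    ripple_lobes: int = 8
    noise_sd_px: float = 0.0
    noise_corr_ascans: float = 0.0  # 0 = iid noise; >0 adds lateral correlation
    laterality: str = "OS"
    center_col: float = 255.5
    center_row: float = 255.5
    rpe_depth_px: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.peak_height_px <= 0:
            raise ParameterError("peak_height_px must be positive")
        if not (self.sigma_major_px >= self.sigma_minor_px > 0):
            raise ParameterError("need sigma_major_px >= sigma_minor_px > 0")
        if not (0.0 <= self.ripple_amp < 0.5):
            raise ParameterError("ripple_amp must lie in [0, 0.5)")
        if self.ripple_amp > 0 and self.ripple_lobes < 3:
            raise ParameterError("ripple_lobes must be >= 3")
        if self.noise_sd_px < 0:
            raise ParameterError("noise_sd_px must be non-negative")
        if self.laterality not in ("OD", "OS"):
            raise ParameterError(f"unknown laterality {self.laterality!r}")


@dataclass
class GroundTruth:
    """Analytic shape values of the noiseless level set of a BumpModel.

    ``theta_true_deg``/``axis_ratio_true`` are the generating parameters;
    the moment-derived fields come from the exact parametric boundary (they
    differ from the parameters only when ripple is present).
    """

    theta_true_deg: float
    axis_ratio_true: float
    sigma_major_px: float
    sigma_minor_px: float
    theta_moment_deg: float
    axis_ratio_moment: float
    circularity: float
    area_ratio: float


def level_set_polygon(model: BumpModel, scale: float = 1.0, n_points: int = 2048) -> Contour:
    """Exact noiseless level-set boundary, in left-eye fundus image coords.

    All level sets share one shape up to the scale factor
    ``sqrt(2*ln(peak/(level-base)))``; pass any positive ``scale``.
    """
    phi = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    rho = scale * (1.0 + model.ripple_amp * np.cos(model.ripple_lobes * phi))
    u = model.sigma_major_px * rho * np.cos(phi)
    v = model.sigma_minor_px * rho * np.sin(phi)
    th = math.radians(model.theta_true_deg)
    dx = u * math.cos(th) - v * math.sin(th)
    dyu = u * math.sin(th) + v * math.cos(th)
    x = model.center_col + dx
    y = model.center_row - dyu  # image rows increase downward
    return Contour(np.column_stack([x, y]))


def ground_truth(model: BumpModel) -> GroundTruth:
    """Analytic shape parameters of the model's level sets."""
    poly = level_set_polygon(model)
    mom = region_moments(poly)
    fit = fit_ellipse_moments(mom)
    return GroundTruth(
        theta_true_deg=wrap_angle_deg(model.theta_true_deg),
        axis_ratio_true=model.sigma_major_px / model.sigma_minor_px,
        sigma_major_px=model.sigma_major_px,
        sigma_minor_px=model.sigma_minor_px,
        theta_moment_deg=fit.theta_deg,
        axis_ratio_moment=axis_ratio(fit),
        circularity=circularity(poly),
        area_ratio=area_ratio(poly.area_S, fit),
    )


def _height_at(model: BumpModel, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Evaluate the analytic thickness surface on a row x col grid."""
    # the displayed (as-acquired) angle: OD eyes are the horizontal mirror of
    # the left-eye frame, so the left-eye-frame truth stays theta_true_deg
    theta_disp = model.theta_true_deg if model.laterality == "OS" else -model.theta_true_deg
    th = math.radians(theta_disp)
    dx = cols[None, :] - model.center_col
    dyu = -(rows[:, None] - model.center_row)
    u = dx * math.cos(th) + dyu * math.sin(th)
    v = -dx * math.sin(th) + dyu * math.cos(th)
    un = u / model.sigma_major_px
    vn = v / model.sigma_minor_px
    rho = np.hypot(un, vn)
    if model.ripple_amp > 0:
        phi = np.arctan2(vn, un)
        rho = rho / (1.0 + model.ripple_amp * np.cos(model.ripple_lobes * phi))
    return model.base_height_px + model.peak_height_px * np.exp(-0.5 * rho**2)


def _correlated_noise(rng: np.random.Generator, shape: tuple[int, int],
                      sd: float, corr_ascans: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    if corr_ascans <= 0:
        return white * sd
    # match the physical correlation length on both axes (rows are ~10x coarser)
    sigma_rows = corr_ascans * (shape[0] - 1) / (N_ASCANS - 1)
    f = ndimage.gaussian_filter(white, sigma=(sigma_rows, corr_ascans), mode="reflect")
    s = f.std()
    if s == 0:
        return np.zeros(shape)
    return f * (sd / s)


def generate_surfaces(model: BumpModel, subject_id: str = "sim") -> tuple[SurfaceStack, GroundTruth]:
    """Render a model into a 49 x 512 segmentation-surface stack.

    The analytic surface is sampled at the 49 B-scan row positions that the
    height-map row interpolation maps back onto the 512-row grid, so a
    noiseless stack reconstructs the bump with only interpolation error.
    The RPE is flat; the ONL/OPL boundary is ``rpe - h`` plus noise.
    """
    rng = np.random.default_rng(model.seed)
    rows = np.linspace(0.0, HI_SIZE - 1.0, N_BSCANS)
    cols = np.arange(N_ASCANS, dtype=float)
    h = _height_at(model, rows, cols)
    if model.noise_sd_px > 0:
        h = h + _correlated_noise(rng, h.shape, model.noise_sd_px, model.noise_corr_ascans)
    h = np.clip(h, 0.0, model.rpe_depth_px)
    rpe = np.full_like(h, model.rpe_depth_px)
    onl = rpe - h
    stack = SurfaceStack(
        onl_depth=onl,
        rpe_depth=rpe,
        subject_id=subject_id,
        laterality=model.laterality,
        axial_range_px=AXIAL_RANGE_PX,
    )
    return stack, ground_truth(model)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class GroupParams:
    """Group-level distributions from which per-subject bump models draw."""

    base_height_px: tuple[float, float] = (14.0, 1.4)       # mean, sd
    peak_height_px: tuple[float, float] = (36.0, 5.0)
    sigma_major_px: tuple[float, float] = (70.0, 8.0)
    axis_ratio: tuple[float, float] = (1.51, 0.35)
    theta_deg: tuple[float, float] = (-6.25, 21.8)
    ripple_amp: tuple[float, float] = (0.13, 0.05)
    ripple_amp_max: float = 0.20
    noise_sd_px: float = 0.5  # manual-corrected segmentation: sub-pixel jitter
    ripple_lobes_choices: tuple[int, ...] = (3, 4)

    def draw(self, rng: np.random.Generator) -> dict:
        def clipped(mean, sd, lo, hi):
            return float(np.clip(rng.normal(mean, sd), lo, hi))

        ratio = clipped(*self.axis_ratio, 1.02, 2.6)
        sig_maj = clipped(*self.sigma_major_px, 40.0, 85.0)
        return dict(
            base_height_px=clipped(*self.base_height_px, 5.0, 40.0),
            peak_height_px=clipped(*self.peak_height_px, 15.0, 80.0),
            sigma_major_px=sig_maj,
            sigma_minor_px=sig_maj / ratio,
            theta_true_deg=clipped(*self.theta_deg, -85.0, 85.0),
            ripple_amp=clipped(*self.ripple_amp, 0.0, self.ripple_amp_max),
            ripple_lobes=int(rng.choice(self.ripple_lobes_choices)),
            noise_sd_px=self.noise_sd_px,
            laterality="OD" if rng.random() < 0.5 else "OS",
        )


# Group defaults emulate the clinical cohort structure the pipeline targets:
# ERM eyes have a thicker ONL base and a more anisotropic, more irregular
# bump; fellow control eyes are smoother and score 0 on the chart. Boundary
# irregularity is low-frequency (3-4 lobes): real ERM contours are irregular
# at large scale yet restorable by five Fourier harmonics, which is what
# lets them pass QC while lowering circularity and area ratio. The ripple
# amplitude distributions are calibrated so the measured group means land
# near circularity 0.79/0.85 and area ratio 0.74/0.76 (ERM/control), with
# QC exclusions rare as in clinical cohorts.
ERM_DEFAULTS = GroupParams(
    base_height_px=(21.7, 2.5),
    peak_height_px=(40.0, 6.0),
    axis_ratio=(1.54, 0.37),
    theta_deg=(-1.28, 29.1),
    ripple_amp=(0.17, 0.05),
    ripple_amp_max=0.22,
)
CONTROL_DEFAULTS = GroupParams()


@dataclass
class MchartLink:
    """Generative link between ground-truth deformation and MH/MV.

    ``log(MH/MV)`` is drawn with correlation ``rho`` to the standardized
    target shape parameter; MV is drawn log-normally and MH = ratio * MV.
    Both scores are then clipped to the chart range [0, 2], quantized to
    0.1 steps, and zeroed below the 0.2-degree chart minimum.
    """

    target: str = "area_ratio"  # column of the ground-truth table
    rho: float = -0.47
    log_ratio_mean: float = 0.29   # ln(0.71 / 0.53): MH tends to exceed MV
    log_ratio_sd: float = 0.5
    log_mv_mean: float = math.log(0.45)
    log_mv_sd: float = 0.5
    quantum: float = 0.1
    chart_min: float = 0.2
    chart_max: float = 2.0

    def quantize(self, score: np.ndarray) -> np.ndarray:
        q = np.round(np.clip(score, 0.0, self.chart_max) / self.quantum) * self.quantum
        q[q < self.chart_min] = 0.0
        return q

    def scores(self, target_values: np.ndarray, rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray]:
        z = np.asarray(target_values, dtype=float)
        sd = z.std()
        z = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)
        eps = rng.standard_normal(z.size)
        log_ratio = self.log_ratio_mean + self.log_ratio_sd * (
            self.rho * z + math.sqrt(max(0.0, 1.0 - self.rho**2)) * eps
        )
        mv = np.exp(rng.normal(self.log_mv_mean, self.log_mv_sd, z.size))
        mh = np.exp(log_ratio) * mv
        return self.quantize(mh), self.quantize(mv)


@dataclass
class CohortSpec:
    """Specification of a simulated two-group cohort."""

    n_erm: int = 39
    n_control: int = 21
    erm: GroupParams = field(default_factory=lambda: replace(ERM_DEFAULTS))
    control: GroupParams = field(default_factory=lambda: replace(CONTROL_DEFAULTS))
    mchart_link: MchartLink = field(default_factory=MchartLink)
    logmar_va_erm: tuple[float, float] = (0.24, 0.16)
    logmar_va_control: tuple[float, float] = (-0.12, 0.03)
    seed: int = 0

    def __post_init__(self):
        if self.n_erm < 1 or self.n_control < 0:
            raise ParameterError("cohort sizes must be positive")


def generate_cohort(
    spec: CohortSpec,
    render_surfaces: bool = True,
) -> tuple[list[SurfaceStack], list[SubjectMeta], pd.DataFrame]:
    """Draw a cohort of subjects; optionally render their surface stacks.

    Per-subject randomness derives from ``(spec.seed, subject index)`` via
    ``numpy`` seed sequences, so individual subjects are reproducible
    independently of cohort size. With ``render_surfaces=False`` only the
    metadata and ground-truth table are produced (fast path for statistical
    calibration studies).
    """
    ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_erm + spec.n_control
    children = ss.spawn(n_total + 1)
    link_rng = np.random.default_rng(children[-1])

    models, groups, ids = [], [], []
    for i in range(n_total):
        group = "ERM" if i < spec.n_erm else "control"
        params = spec.erm if group == "ERM" else spec.control
        rng = np.random.default_rng(children[i])
        draw = params.draw(rng)
        subject_seed = int(rng.integers(0, 2**31 - 1))
        models.append(BumpModel(seed=subject_seed, **draw))
        groups.append(group)
        ids.append(f"sim{i:03d}")

    truths = [ground_truth(m) for m in models]
    truth_df = pd.DataFrame([{
        "subject_id": sid,
        "group": grp,
        "laterality": m.laterality,
        "theta_true_deg": t.theta_true_deg,
        "axis_ratio_true": t.axis_ratio_true,
        "theta_moment_deg": t.theta_moment_deg,
        "axis_ratio_moment": t.axis_ratio_moment,
        "circularity_true": t.circularity,
        "area_ratio_true": t.area_ratio,
        "base_height_px": m.base_height_px,
        "peak_height_px": m.peak_height_px,
        "ripple_amp": m.ripple_amp,
        "ripple_lobes": m.ripple_lobes,
        "noise_sd_px": m.noise_sd_px,
        "seed": m.seed,
    } for sid, grp, m, t in zip(ids, groups, models, truths)])

    # MCHART scores: linked to ground-truth deformation for ERM eyes,
    # zero (no detected distortion) for fellow control eyes
    target_col = {
        "area_ratio": "area_ratio_true",
        "axis_ratio": "axis_ratio_moment",
        "circularity": "circularity_true",
        "axis_angle": "theta_moment_deg",
    }.get(spec.mchart_link.target, spec.mchart_link.target)
    erm_mask = truth_df["group"] == "ERM"
    mh = np.zeros(n_total)
    mv = np.zeros(n_total)
    mh_erm, mv_erm = spec.mchart_link.scores(
        truth_df.loc[erm_mask, target_col].to_numpy(), link_rng
    )
    mh[erm_mask.to_numpy()] = mh_erm
    mv[erm_mask.to_numpy()] = mv_erm

    metas = []
    for i, (sid, grp, m) in enumerate(zip(ids, groups, models)):
        va_mean, va_sd = spec.logmar_va_erm if grp == "ERM" else spec.logmar_va_control
        va = float(np.round(link_rng.normal(va_mean, va_sd), 2))
        metas.append(SubjectMeta(
            subject_id=sid, group=grp, laterality=m.laterality,
            mh=float(np.round(mh[i], 2)), mv=float(np.round(mv[i], 2)),
            logmar_va=va,
        ))

    stacks = []
    if render_surfaces:
        for sid, m in zip(ids, models):
            stack, _ = generate_surfaces(m, subject_id=sid)
            stacks.append(stack)
    return stacks, metas, truth_df


def simulate_to_dir(spec: CohortSpec, out_dir) -> pd.DataFrame:
    """Render a cohort to disk: per-subject ``.surf.txt`` files plus
    ``subjects.csv`` and ``ground_truth.csv``. Returns the truth table."""
    import json
    from pathlib import Path

    from .surface_io import write_subject_table, write_surface_stack

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stacks, metas, truth = generate_cohort(spec, render_surfaces=True)
    for stack in stacks:
        write_surface_stack(stack, out / f"{stack.subject_id}.surf.txt")
    write_subject_table(metas, out / "subjects.csv")
    truth.to_csv(out / "ground_truth.csv", index=False, float_format="%.6f")
    (out / "simulation_meta.json").write_text(json.dumps({
        "seed": spec.seed, "n_erm": spec.n_erm, "n_control": spec.n_control,
        "mchart_link": {"target": spec.mchart_link.target, "rho": spec.mchart_link.rho},
    }, indent=2))
    return truth
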