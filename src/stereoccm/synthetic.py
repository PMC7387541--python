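"""Synthetic CCM data: images, ground-truth annotations, focus regions, cohorts.

The generator emulates the statistical structure the analysis assumes:

* main fibers as smoothed oriented line processes — headings drawn from a von
  Mises distribution on the doubled angle around a stratum-specific dominant
  direction (vertical 90°, diagonal-right 30°, diagonal-left 150°), with a
  small random-walk curvature;
* per image, fibers accumulate until the configured fiber intensity (mm of
  main fiber per mm² of frame) is met exactly — the last fiber is trimmed at
  the target arclength, so the per-image ground-truth length is exact;
* branch points dropped along fibers as a Poisson process (``branch_rate``
  per mm) with short branch polylines grown from them;
* a star-shaped in-focus region (low-order harmonic perturbation of a disk)
  about the image center; structures outside it are invisible to a tracer
  — the *visible* annotation is the truth clipped to the region;
* optional rendering: Gaussian fiber cross-sections, Gaussian defocus blur
  outside the focus region, additive Gaussian read noise on the 8-bit range;
* multi-group cohorts with per-group multiplicative effects on fiber
  intensity and branch rate, log-normal between-subject variation, and
  synthetic IENFD with a configurable correlation to the subject's true
  fiber intensity (``ienfd_rho = 0`` reproduces the no-correlation regime).

Default group sizes are 26 controls / 45 DSPN(−) / 17 DSPN(+).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from shapely.geometry import LineString, MultiLineString
from shapely.geometry import box as shapely_box

from .data_model import (
    GROUPS,
    FocusRegion,
    ImageMeta,
    NerveAnnotation,
    ValidationError,
    write_annotation,
    write_focus_region,
)
from .focus_area import polygon_area, region_polygon, full_frame_region, _frame_distance
from .metrics import clip_to_region

__all__ = [
    "SynthParams",
    "SyntheticImage",
    "SyntheticSubject",
    "Cohort",
    "generate_image",
    "generate_cohort",
    "render_image",
    "write_cohort",
]

_STRATUM_ANGLE_DEG = {"vertical": 90.0, "diagonal_right": 30.0, "diagonal_left": 150.0}


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration.

    Rates and effect sizes default to the magnitudes reported for adjusted
    corneal nerve metrics in healthy controls and diabetic groups: a control
    fiber intensity of 18 mm/mm² with ~2.2 branch points per mm of fiber
    yields CNFL ≈ 19–20 mm/mm² and CNBD ≈ 40–45 no./mm²; the group
    multipliers (1.0, 0.83, 0.60) on intensity and (1.0, 0.85, 0.72) on
    branch rate mirror the control : DSPN(−) : DSPN(+) separation.
    """

    fiber_intensity: float = 18.0      # mm of main fiber per mm² of frame
    branch_rate: float = 2.2           # branch points per mm of main fiber
    branch_length_um: float = 25.0     # mean branch length (exponential)
    orientation_kappa: float = 8.0     # von Mises concentration on the doubled angle
    curvature_sd_deg: float = 2.5      # heading random walk per 10 µm step
    step_um: float = 10.0
    focus_radius_um: float = 185.0     # mean radius of the in-focus region
    focus_irregularity: float = 0.15   # harmonic perturbation amplitude
    full_focus: bool = False           # in-focus region = whole frame
    blur_sigma_out: float = 8.0        # defocus blur outside the region, px
    noise_sd: float = 10.0             # additive Gaussian noise, gray levels
    fiber_sigma_px: float = 1.3        # fiber cross-section, px
    fiber_amplitude: float = 110.0     # peak fiber brightness over background
    background: float = 30.0
    group_fiber_effects: tuple = (1.0, 0.83, 0.60)
    group_branch_effects: tuple = (1.0, 0.85, 0.72)
    subject_cv: float = 0.30           # between-subject CV of fiber intensity
    group_sizes: tuple = (26, 45, 17)  # control, dspn_minus, dspn_plus
    images_per_subject: int = 16
    orientation_mix: tuple = (6, 5, 5)  # vertical, diagonal_left, diagonal_right
    ienfd_means: tuple = (8.5, 7.0, 4.5)  # fibers/mm by group
    ienfd_sd: float = 3.0
    ienfd_rho: float = 0.0             # correlation with subject fiber intensity
    width_px: int = 380
    height_px: int = 380
    fov_um: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.fiber_intensity, self.branch_rate, self.noise_sd) < 0:
            raise ValidationError("rates must be ≥ 0")
        if self.images_per_subject != sum(self.orientation_mix):
            raise ValidationError("orientation_mix must sum to images_per_subject")
        if len(self.group_sizes) != len(GROUPS):
            raise ValidationError(f"group_sizes must have {len(GROUPS)} entries")


@dataclass
class SyntheticImage:
    meta: ImageMeta
    truth: NerveAnnotation          # everything, in focus or not
    visible: NerveAnnotation        # truth clipped to the in-focus region
    region: FocusRegion             # boundary only; a_after estimated downstream
    true_area_um2: float            # exact polygon area of the region
    orientation: str
    image: np.ndarray | None = None


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    fiber_intensity: float
    branch_rate: float
    ienfd: float
    images: list = field(default_factory=list)


@dataclass
class Cohort:
    params: SynthParams
    subjects: list = field(default_factory=list)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for im in s.images:
                rows.append(
                    {
                        "subject_id": s.subject_id,
                        "group": s.group,
                        "image_id": im.meta.image_id,
                        "acquisition_index": im.meta.acquisition_index,
                        "orientation": im.orientation,
                        "ienfd": s.ienfd,
                        "true_fiber_intensity": s.fiber_intensity,
                        "true_area_um2": im.true_area_um2,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Single-image generation
# ---------------------------------------------------------------------------


def _trim_polyline(poly: np.ndarray, target_um: float) -> np.ndarray | None:
    """Truncate a polyline at an exact arclength; None if target is ~zero."""
    if target_um <= 1e-9:
        return None
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if target_um >= cum[-1]:
        return poly
    j = int(np.searchsorted(cum, target_um))
    frac = (target_um - cum[j - 1]) / seg[j - 1]
    cut = poly[j - 1] + frac * (poly[j] - poly[j - 1])
    return np.vstack([poly[:j], cut])


def _sample_fiber(rng: np.random.Generator, theta0_deg: float, p: SynthParams) -> np.ndarray | None:
    """One smoothed oriented fiber clipped to the frame (list of pieces).

    Fibers follow the uniform (θ, offset) line parametrization — orientation
    from the von Mises mode, then a uniform signed offset across the frame's
    projection onto the fiber normal — which makes the straight-line process
    spatially homogeneous (no central over-coverage); the small random-walk
    curvature perturbs this only marginally.
    """
    fov = p.fov_um
    theta = 0.5 * rng.vonmises(2 * math.radians(theta0_deg), p.orientation_kappa)
    d = np.array([math.cos(theta), math.sin(theta)])
    nrm = np.array([-d[1], d[0]])
    # mean-reverting heading: stationary waviness without long-range lateral
    # drift, so the uniform-offset band stays homogeneous across the frame
    alpha = 0.88
    sd_step = math.radians(p.curvature_sd_deg)
    sd_stat = sd_step / math.sqrt(1.0 - alpha * alpha) if p.curvature_sd_deg > 0 else 0.0
    margin = 80.0  # head-room beyond the exact projection half-width
    half_width = 0.5 * fov * (abs(nrm[0]) + abs(nrm[1])) + margin
    offset = rng.uniform(-half_width, half_width)
    center = np.array([fov / 2.0, fov / 2.0]) + offset * nrm
    half_span = 0.75 * fov * (abs(d[0]) + abs(d[1])) + margin
    start = center - half_span * d
    n_steps = int(math.ceil(2 * half_span / p.step_um))
    pts = [start]
    dev = rng.normal(0.0, sd_stat) if sd_stat > 0 else 0.0
    pos = start.copy()
    for _ in range(n_steps):
        dev = alpha * dev + rng.normal(0.0, sd_step)
        heading = theta + dev
        pos = pos + p.step_um * np.array([math.cos(heading), math.sin(heading)])
        pts.append(pos.copy())
    line = LineString(pts).intersection(shapely_box(0.0, 0.0, fov, fov))
    if line.is_empty:
        return []
    if isinstance(line, MultiLineString):
        geoms = list(line.geoms)
    elif isinstance(line, LineString):
        geoms = [line]
    else:  # GeometryCollection from a grazing contact
        geoms = [g for g in line.geoms if isinstance(g, LineString)]
    # every in-frame piece is kept (a wavy fiber may exit and re-enter);
    # all pieces belong to the same fiber identity
    return [
        np.asarray(g.coords, dtype=float)
        for g in geoms
        if g.length > 0 and len(g.coords) >= 2
    ]


def _point_on_polyline(poly: np.ndarray, s_um: float) -> tuple:
    """(point, tangent angle) at arclength ``s_um`` along the polyline."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s_um = min(max(s_um, 0.0), cum[-1])
    j = max(int(np.searchsorted(cum, s_um, side="right")) - 1, 0)
    j = min(j, len(seg) - 1)
    frac = 0.0 if seg[j] == 0 else (s_um - cum[j]) / seg[j]
    pt = poly[j] + frac * (poly[j + 1] - poly[j])
    d = poly[j + 1] - poly[j]
    return pt, math.atan2(d[1], d[0])


def _sample_branches(
    rng: np.random.Generator, fiber: np.ndarray, branch_rate: float, p: SynthParams
) -> tuple:
    """Poisson branch points along a fiber plus short branch polylines."""
    length_mm = float(np.linalg.norm(np.diff(fiber, axis=0), axis=1).sum()) / 1000.0
    n = rng.poisson(branch_rate * length_mm)
    points, polylines = [], []
    if n == 0:
        return points, polylines
    frame = shapely_box(0.0, 0.0, p.fov_um, p.fov_um)
    total_um = length_mm * 1000.0
    for s in np.sort(rng.uniform(0.0, total_um, size=n)):
        origin, tangent = _point_on_polyline(fiber, float(s))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        angle = tangent + sign * math.radians(rng.uniform(35.0, 75.0))
        blen = float(np.clip(rng.exponential(p.branch_length_um), 8.0, 80.0))
        nseg = 3
        pts = [origin]
        heading = angle
        for _ in range(nseg):
            heading += math.radians(rng.normal(0.0, 4.0))
            pts.append(pts[-1] + (blen / nseg) * np.array([math.cos(heading), math.sin(heading)]))
        geom = LineString(pts).intersection(frame)
        if isinstance(geom, MultiLineString):
            # keep the piece that starts at the origin
            geom = min(geom.geoms, key=lambda g: LineString(g).distance(LineString([origin, origin + 1e-6])))
        if not isinstance(geom, LineString) or geom.length <= 0 or len(geom.coords) < 2:
            continue
        points.append(origin)
        polylines.append(np.asarray(geom.coords, dtype=float))
    return points, polylines


def _sample_focus_region(rng: np.random.Generator, p: SynthParams, image_id: str) -> FocusRegion:
    """Star-shaped region: disk radius perturbed by 2nd–4th harmonics.

    Stored as a 64-vertex boundary polygon (vertices on the radial function),
    so the nucleator and the clipper see exactly the same geometry.
    """
    fov = p.fov_um
    center = np.array([fov / 2.0, fov / 2.0])
    if p.full_focus:
        return full_frame_region(ImageMeta(image_id=image_id, width_px=p.width_px,
                                           height_px=p.height_px, fov_um=fov),
                                 image_id=image_id)
    n = 64
    angles = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    r = np.full(n, p.focus_radius_um)
    for k in (2, 3, 4):
        amp = p.focus_irregularity * rng.uniform(0.4, 1.0) / (k - 1)
        phase = rng.uniform(0.0, 2 * math.pi)
        r = r * (1.0 + amp * np.cos(k * angles + phase))
    rmax = _frame_distance(center, angles, fov) - 1e-6
    r = np.clip(r, 20.0, rmax)
    boundary = center + r[:, None] * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    return FocusRegion(image_id=image_id, center=center, boundary=boundary)


def generate_image(
    params: SynthParams,
    seed,
    orientation: str = "vertical",
    image_id: str = "synthetic",
    subject_id: str = "",
    acquisition_index: int = 0,
    fiber_intensity: float | None = None,
    branch_rate: float | None = None,
    render: bool = False,
) -> SyntheticImage:
    """Generate one image worth of ground truth (and optionally pixels).

    The total in-frame main-fiber length equals ``fiber_intensity ×
    frame_area`` exactly (the last fiber is trimmed), so the per-image
    ground-truth CNFL over the full frame is exact.
    """
    if orientation not in _STRATUM_ANGLE_DEG:
        raise ValidationError(f"unknown orientation {orientation!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = params
    intensity = p.fiber_intensity if fiber_intensity is None else fiber_intensity
    brate = p.branch_rate if branch_rate is None else branch_rate
    meta = ImageMeta(
        image_id=image_id,
        subject_id=subject_id,
        acquisition_index=acquisition_index,
        width_px=p.width_px,
        height_px=p.height_px,
        fov_um=p.fov_um,
    )
    target_um = intensity * meta.frame_area_mm2 * 1000.0  # mm/mm² → µm in frame
    theta0 = _STRATUM_ANGLE_DEG[orientation]
    fibers: list = []
    fiber_ids: list = []
    total = 0.0
    guard = 0
    next_id = 0
    while total < target_um - 1e-9 and guard < 10000:
        guard += 1
        pieces = _sample_fiber(rng, theta0, p)
        if not pieces:
            continue
        fid = next_id
        for piece in pieces:
            flen = float(np.linalg.norm(np.diff(piece, axis=0), axis=1).sum())
            if total + flen > target_um:
                piece = _trim_polyline(piece, target_um - total)
                if piece is None or piece.shape[0] < 2:
                    total = target_um
                    break
                flen = float(np.linalg.norm(np.diff(piece, axis=0), axis=1).sum())
            fibers.append(piece)
            fiber_ids.append(fid)
            total += flen
            if total >= target_um - 1e-9:
                break
        if fid in fiber_ids:
            next_id += 1
    branch_points: list = []
    branches: list = []
    for fiber in fibers:
        pts, lines = _sample_branches(rng, fiber, brate, p)
        branch_points.extend(pts)
        branches.extend(lines)
    truth = NerveAnnotation(
        image_id=image_id,
        main_fibers=fibers,
        branches=branches,
        branch_points=np.asarray(branch_points, dtype=float).reshape(-1, 2),
        main_fiber_ids=fiber_ids,
    )
    region = _sample_focus_region(rng, p, image_id)
    true_area = polygon_area(region.boundary)
    visible = clip_to_region(truth, region, fov_um=p.fov_um)
    out = SyntheticImage(
        meta=meta,
        truth=truth,
        visible=visible,
        region=FocusRegion(image_id=image_id, center=region.center, boundary=region.boundary),
        true_area_um2=true_area,
        orientation=orientation,
    )
    if render:
        out.image = render_image(truth, region, meta, p, rng)
    return out


def render_image(
    truth: NerveAnnotation,
    region: FocusRegion,
    meta: ImageMeta,
    params: SynthParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rasterize fibers with Gaussian cross-sections, defocus outside the
    region, add read noise; returns an 8-bit grayscale array."""
    p = params
    h, w = meta.height_px, meta.width_px
    scale = meta.um_per_px
    canvas = np.zeros((h, w), dtype=float)
    for poly in list(truth.main_fibers) + list(truth.branches):
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        total = seg.sum()
        if total <= 0:
            continue
        n_samples = max(int(total / (0.25 * scale)), 2)
        s = np.linspace(0.0, total, n_samples)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        j = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
        frac = np.where(seg[j] > 0, (s - cum[j]) / np.where(seg[j] > 0, seg[j], 1.0), 0.0)
        pts = poly[j] + frac[:, None] * (poly[j + 1] - poly[j])
        xs = np.clip(np.round(pts[:, 0] / scale - 0.5).astype(int), 0, w - 1)
        ys = np.clip(np.round(pts[:, 1] / scale - 0.5).astype(int), 0, h - 1)
        canvas[ys, xs] = 1.0
    smooth = ndi.gaussian_filter(canvas, p.fiber_sigma_px)
    peak = 1.0 / (p.fiber_sigma_px * math.sqrt(2 * math.pi))
    sharp = p.background + (p.fiber_amplitude / peak) * smooth

    poly = region_polygon(region)
    from skimage.draw import polygon as draw_polygon

    mask = np.zeros((h, w), dtype=bool)
    ext = np.asarray(poly.exterior.coords)
    rr, cc = draw_polygon(ext[:, 1] / scale - 0.5, ext[:, 0] / scale - 0.5, shape=(h, w))
    mask[rr, cc] = True
    if p.blur_sigma_out > 0 and not mask.all():
        blurred = ndi.gaussian_filter(sharp, p.blur_sigma_out)
        img = np.where(mask, sharp, blurred)
    else:
        img = sharp
    img = img + rng.normal(0.0, p.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 255.0).astype(np.uint8)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def generate_cohort(params: SynthParams, render: bool = False) -> Cohort:
    """Generate a full multi-group cohort, deterministic in ``params.seed``.

    Per-subject child seeds derive from (group index, subject index) spawn
    keys, so regenerating with the same parameters is byte-identical.
    """
    p = params
    sigma = math.sqrt(math.log(1.0 + p.subject_cv**2))
    subjects = []
    for gi, (group, n_g) in enumerate(zip(GROUPS, p.group_sizes)):
        for si in range(n_g):
            rng = np.random.default_rng(np.random.SeedSequence(p.seed, spawn_key=(gi, si)))
            subject_id = f"{group}_{si:03d}"
            z = rng.normal()
            intensity = (
                p.fiber_intensity
                * p.group_fiber_effects[gi]
                * math.exp(sigma * z - sigma**2 / 2.0)
            )
            brate = p.branch_rate * p.group_branch_effects[gi]
            z2 = rng.normal()
            rho = p.ienfd_rho
            ienfd = p.ienfd_means[gi] + p.ienfd_sd * (rho * z + math.sqrt(1 - rho**2) * z2)
            ienfd = max(ienfd, 0.3)
            orientations = [
                o
                for o, k in zip(("vertical", "diagonal_left", "diagonal_right"), p.orientation_mix)
                for _ in range(k)
            ]
            rng.shuffle(orientations)
            images = []
            for ai, orient in enumerate(orientations):
                images.append(
                    generate_image(
                        p,
                        rng,
                        orientation=orient,
                        image_id=f"{subject_id}_img{ai:02d}",
                        subject_id=subject_id,
                        acquisition_index=ai,
                        fiber_intensity=intensity,
                        branch_rate=brate,
                        render=render,
                    )
                )
            subjects.append(
                SyntheticSubject(
                    subject_id=subject_id,
                    group=group,
                    fiber_intensity=intensity,
                    branch_rate=brate,
                    ienfd=float(ienfd),
                    images=images,
                )
            )
    return Cohort(params=p, subjects=subjects)


def write_cohort(cohort: Cohort, outdir, write_truth: bool = True) -> None:
    """Write a cohort to disk: visible annotations, regions, manifest, images."""
    out = Path(outdir)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    (out / "regions").mkdir(exist_ok=True)
    if write_truth:
        (out / "truth").mkdir(exist_ok=True)
    have_images = any(im.image is not None for s in cohort.subjects for im in s.images)
    if have_images:
        (out / "images").mkdir(exist_ok=True)
        import imageio.v3 as iio
    for s in cohort.subjects:
        for im in s.images:
            write_annotation(im.visible, im.meta, out / "annotations" / f"{im.meta.image_id}.json")
            write_focus_region(im.region, out / "regions" / f"{im.meta.image_id}.json")
            if write_truth:
                write_annotation(im.truth, im.meta, out / "truth" / f"{im.meta.image_id}.json")
            if im.image is not None:
                iio.imwrite(out / "images" / f"{im.meta.image_id}.png", im.image)
    cohort.manifest().to_csv(out / "manifest.csv", index=False)
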