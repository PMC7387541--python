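"""Core data types and file I/O for corneal confocal microscopy (CCM) analysis.

Coordinate convention
---------------------
All geometry is held in continuous micrometre (µm) coordinates with the origin
at the top-left image corner, x rightward and y downward.  The centre of
raster pixel ``(i, j)`` (row, column) maps to ``((j + 0.5)·s, (i + 0.5)·s)``
where ``s = fov_um / width_px`` is the pixel pitch.  Vertex coordinates stored
in *pixel units* in annotation files are continuous positions and convert by
plain scaling (no half-pixel shift); the half-pixel rule applies only to
raster cells when rendering or tracing.

File formats
------------
Annotations are stored as JSON::

    {"image_id": ..., "units": "um" | "px",
     "meta": {"width_px": ..., "height_px": ..., "fov_um": ...,
              "subject_id": ..., "eye": ..., "acquisition_index": ...},
     "main_fibers": [[[x, y], ...], ...],
     "branches":    [[[x, y], ...], ...],
     "branch_points": [[x, y], ...]}

A CSV dialect with columns ``trace_id, kind, vertex_index, x_um, y_um`` (or
``x_px, y_px``) is accepted for hand-made fixtures; ``kind`` is one of
``main``, ``branch``, ``branch_point``.  Focus-region delineations are JSON
with either a closed ``polygon`` or a table of ``rays`` ``[{"angle": radians,
"l": µm}, ...]``.  Result tables are UTF-8 CSV with '.' decimal separator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "ORIENTATIONS",
    "EYES",
    "METRIC_NAMES",
    "ValidationError",
    "ParseError",
    "ImageMeta",
    "NerveAnnotation",
    "FocusRegion",
    "CCMMetrics",
    "SubjectRecord",
    "um_per_px",
    "polyline_length",
    "read_annotation",
    "write_annotation",
    "read_focus_region",
    "write_focus_region",
    "read_results",
    "write_results",
]

GROUPS = ("control", "dspn_minus", "dspn_plus")
ORIENTATIONS = ("vertical", "diagonal_left", "diagonal_right")
EYES = ("left", "right", "unknown")
METRIC_NAMES = ("cnfl", "cnfd", "cnbd")
MODES = ("unadjusted", "adjusted")

#: coordinate slack (µm) tolerated when validating bounds, to absorb
#: floating-point round-off from clipping and unit conversion
_BOUNDS_EPS = 1e-6


class ValidationError(ValueError):
    """An object violates a documented invariant."""


class ParseError(ValueError):
    """A file does not conform to the documented schema."""


@dataclass(frozen=True)
class ImageMeta:
    """Acquisition metadata for one CCM image.

    The default frame follows the HRT-with-Rostock-module convention used
    throughout: 380 × 380 pixels covering a 400 × 400 µm² field of view.
    """

    image_id: str
    subject_id: str = ""
    eye: str = "unknown"
    acquisition_index: int = 0
    width_px: int = 380
    height_px: int = 380
    fov_um: float = 400.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValidationError(
                f"{self.image_id!r}: image dimensions must be positive, got "
                f"{self.width_px} × {self.height_px}"
            )
        if self.fov_um <= 0:
            raise ValidationError(f"{self.image_id!r}: fov_um must be positive")
        if self.acquisition_index < 0:
            raise ValidationError(f"{self.image_id!r}: acquisition_index must be ≥ 0")
        if self.eye not in EYES:
            raise ValidationError(f"{self.image_id!r}: eye must be one of {EYES}")

    @property
    def um_per_px(self) -> float:
        return self.fov_um / self.width_px

    @property
    def frame_area_um2(self) -> float:
        return self.fov_um * self.fov_um

    @property
    def frame_area_mm2(self) -> float:
        return self.frame_area_um2 / 1e6


def um_per_px(meta: ImageMeta) -> float:
    """Pixel pitch in µm/px, i.e. ``fov_um / width_px`` (400/380 ≈ 1.0526 at
    the default frame)."""
    return meta.um_per_px


def polyline_length(vertices: np.ndarray) -> float:
    """Arc length of a polyline given as an (n, 2) vertex array."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
        raise ValidationError("polyline must be an (n≥2, 2) array")
    return float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum())


def _as_polyline(obj, label: str) -> np.ndarray:
    try:
        arr = np.asarray(obj, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{label}: vertices are not numeric") from exc
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ParseError(f"{label}: expected an (n, 2) vertex list")
    if arr.shape[0] < 2:
        raise ValidationError(f"{label}: a polyline needs at least 2 vertices")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{label}: non-finite coordinate")
    return arr


def _as_points(obj, label: str) -> np.ndarray:
    arr = np.asarray(obj, dtype=float)
    if arr.size == 0:
        return np.zeros((0, 2))
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ParseError(f"{label}: expected an (n, 2) point list")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{label}: non-finite coordinate")
    return arr


@dataclass(eq=False)
class NerveAnnotation:
    """Traced nerve structures of one image, in µm coordinates.

    ``main_fibers`` and ``branches`` are lists of (n, 2) polyline vertex
    arrays; ``branch_points`` is an (m, 2) array whose row count is the
    numerator of CNBD for the image.  ``main_fiber_ids`` optionally maps each
    polyline in ``main_fibers`` back to an original fiber identity: clipping
    may split one fiber into several retained pieces, and a split fiber must
    still count once toward CNFD.
    """

    image_id: str
    main_fibers: list = field(default_factory=list)
    branches: list = field(default_factory=list)
    branch_points: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    main_fiber_ids: list | None = None

    def __post_init__(self) -> None:
        self.main_fibers = [
            _as_polyline(p, f"main_fibers[{i}]") for i, p in enumerate(self.main_fibers)
        ]
        self.branches = [
            _as_polyline(p, f"branches[{i}]") for i, p in enumerate(self.branches)
        ]
        self.branch_points = _as_points(self.branch_points, "branch_points")
        if self.main_fiber_ids is not None:
            self.main_fiber_ids = [int(i) for i in self.main_fiber_ids]
            if len(self.main_fiber_ids) != len(self.main_fibers):
                raise ValidationError(
                    "main_fiber_ids must parallel main_fibers "
                    f"({len(self.main_fiber_ids)} ids for {len(self.main_fibers)} polylines)"
                )

    # -- derived quantities -------------------------------------------------

    @property
    def n_main_fibers(self) -> int:
        """Number of distinct main fibers (fragments of one fiber count once)."""
        if self.main_fiber_ids is not None:
            return len(set(self.main_fiber_ids))
        return len(self.main_fibers)

    @property
    def n_branch_points(self) -> int:
        return int(self.branch_points.shape[0])

    @property
    def main_length_um(self) -> float:
        return float(sum(polyline_length(p) for p in self.main_fibers))

    @property
    def branch_length_um(self) -> float:
        return float(sum(polyline_length(p) for p in self.branches))

    @property
    def total_length_um(self) -> float:
        return self.main_length_um + self.branch_length_um

    def is_empty(self) -> bool:
        return not self.main_fibers and not self.branches and self.n_branch_points == 0

    # -- validation / transforms --------------------------------------------

    def validate_bounds(self, fov_um: float) -> "NerveAnnotation":
        """Check every coordinate lies within [0, fov_um]²."""
        lo, hi = -_BOUNDS_EPS, fov_um + _BOUNDS_EPS
        for label, arrays in (
            ("main_fibers", self.main_fibers),
            ("branches", self.branches),
            ("branch_points", [self.branch_points] if self.branch_points.size else []),
        ):
            for i, arr in enumerate(arrays):
                if arr.size and (arr.min() < lo or arr.max() > hi):
                    bad = arr[((arr < lo) | (arr > hi)).any(axis=1)][0]
                    raise ValidationError(
                        f"{self.image_id!r}: {label}[{i}] vertex ({bad[0]:g}, {bad[1]:g}) "
                        f"outside the [0, {fov_um:g}] µm frame"
                    )
        return self

    def scaled(self, s: float) -> "NerveAnnotation":
        """All coordinates multiplied by ``s`` (for unit-coherence checks)."""
        return NerveAnnotation(
            image_id=self.image_id,
            main_fibers=[p * s for p in self.main_fibers],
            branches=[p * s for p in self.branches],
            branch_points=self.branch_points * s,
            main_fiber_ids=None if self.main_fiber_ids is None else list(self.main_fiber_ids),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, NerveAnnotation):
            return NotImplemented
        return (
            self.image_id == other.image_id
            and len(self.main_fibers) == len(other.main_fibers)
            and len(self.branches) == len(other.branches)
            and all(np.array_equal(a, b) for a, b in zip(self.main_fibers, other.main_fibers))
            and all(np.array_equal(a, b) for a, b in zip(self.branches, other.branches))
            and np.array_equal(self.branch_points, other.branch_points)
        )


@dataclass(eq=False)
class FocusRegion:
    """Star-shaped in-focus delineation of one image.

    The boundary is given either as a closed polygon (vertex array, first
    vertex not repeated) or as a table of rays ``(angle, l)`` measured from
    ``center``; both in µm.  After nucleator estimation, ``ray_angles`` /
    ``ray_lengths`` hold the systematic test rays actually used and
    ``a_after`` the estimated in-focus area (µm²).
    """

    image_id: str
    center: np.ndarray = field(default_factory=lambda: np.array([200.0, 200.0]))
    boundary: np.ndarray | None = None
    ray_angles: np.ndarray | None = None
    ray_lengths: np.ndarray | None = None
    a_after: float | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        if self.boundary is not None:
            b = np.asarray(self.boundary, dtype=float)
            if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] < 3:
                raise ValidationError(
                    f"{self.image_id!r}: boundary must be an (n≥3, 2) polygon"
                )
            self.boundary = b
        if (self.ray_angles is None) != (self.ray_lengths is None):
            raise ValidationError("ray_angles and ray_lengths must be given together")
        if self.ray_angles is not None:
            self.ray_angles = np.asarray(self.ray_angles, dtype=float).ravel()
            self.ray_lengths = np.asarray(self.ray_lengths, dtype=float).ravel()
            if self.ray_angles.shape != self.ray_lengths.shape:
                raise ValidationError("ray_angles and ray_lengths must have equal length")
            if np.any(self.ray_lengths <= 0):
                raise ValidationError(f"{self.image_id!r}: every ray length must be > 0")
        if self.boundary is None and self.ray_angles is None:
            raise ValidationError(
                f"{self.image_id!r}: a focus region needs a boundary polygon or a ray table"
            )
        if self.a_after is not None and self.a_after <= 0:
            raise ValidationError(f"{self.image_id!r}: a_after must be > 0")


@dataclass(frozen=True)
class CCMMetrics:
    """CNFL (mm/mm²), CNFD (no./mm²) and CNBD (no./mm²) over a reference area."""

    cnfl: float
    cnfd: float
    cnbd: float
    reference_area_mm2: float
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.reference_area_mm2 <= 0:
            raise ValidationError("reference_area_mm2 must be > 0")
        if min(self.cnfl, self.cnfd, self.cnbd) < 0:
            raise ValidationError("CCM metrics must be ≥ 0")

    def as_tuple(self) -> tuple:
        return (self.cnfl, self.cnfd, self.cnbd)


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject averaged metrics plus clinical label and optional IENFD."""

    subject_id: str
    group: str
    metrics_adjusted: CCMMetrics
    metrics_unadjusted: CCMMetrics
    ienfd: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.metrics_adjusted.mode != "adjusted":
            raise ValidationError("metrics_adjusted must have mode='adjusted'")
        if self.metrics_unadjusted.mode != "unadjusted":
            raise ValidationError("metrics_unadjusted must have mode='unadjusted'")

    def metrics(self, mode: str) -> CCMMetrics:
        if mode == "adjusted":
            return self.metrics_adjusted
        if mode == "unadjusted":
            return self.metrics_unadjusted
        raise ValidationError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------


def _meta_from_json(obj: dict, image_id: str) -> ImageMeta:
    m = obj.get("meta", {})
    return ImageMeta(
        image_id=image_id,
        subject_id=str(m.get("subject_id", "")),
        eye=str(m.get("eye", "unknown")),
        acquisition_index=int(m.get("acquisition_index", 0)),
        width_px=int(m.get("width_px", 380)),
        height_px=int(m.get("height_px", 380)),
        fov_um=float(m.get("fov_um", 400.0)),
    )


def read_annotation(path, meta: ImageMeta | None = None) -> NerveAnnotation:
    """Read a nerve annotation from JSON (native schema) or CSV (fixture dialect).

    Coordinates stored in pixel units are converted to µm with the scale
    ``fov_um / width_px`` taken from the file's own meta block (JSON) or from
    the ``meta`` argument (CSV with ``x_px``/``y_px`` columns).  The result is
    validated against the frame bounds.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_annotation_csv(path, meta)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    if "image_id" not in obj:
        raise ParseError(f"{path}: missing required key 'image_id'")
    image_id = str(obj["image_id"])
    file_meta = _meta_from_json(obj, image_id)
    use_meta = meta if meta is not None else file_meta
    scale = 1.0
    units = obj.get("units", "um")
    if units == "px":
        scale = use_meta.um_per_px
    elif units != "um":
        raise ParseError(f"{path}: units must be 'um' or 'px', got {units!r}")
    try:
        ann = NerveAnnotation(
            image_id=image_id,
            main_fibers=[np.asarray(p, dtype=float) * scale for p in obj.get("main_fibers", [])],
            branches=[np.asarray(p, dtype=float) * scale for p in obj.get("branches", [])],
            branch_points=np.asarray(obj.get("branch_points", []), dtype=float).reshape(-1, 2)
            * scale,
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, (ParseError, ValidationError)):
            raise
        raise ParseError(f"{path}: malformed coordinate data ({exc})") from exc
    return ann.validate_bounds(use_meta.fov_um)


def _read_annotation_csv(path: Path, meta: ImageMeta | None) -> NerveAnnotation:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    required = {"trace_id", "kind", "vertex_index"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: CSV must have columns {sorted(required)} plus coordinates")
    if {"x_um", "y_um"}.issubset(df.columns):
        xcol, ycol, scale = "x_um", "y_um", 1.0
    elif {"x_px", "y_px"}.issubset(df.columns):
        if meta is None:
            raise ParseError(f"{path}: pixel-space CSV requires an ImageMeta for scaling")
        xcol, ycol, scale = "x_px", "y_px", meta.um_per_px
    else:
        raise ParseError(f"{path}: CSV needs x_um/y_um or x_px/y_px columns")
    main, branches, points = [], [], []
    for (tid, kind), grp in df.groupby(["trace_id", "kind"], sort=True):
        grp = grp.sort_values("vertex_index")
        coords = grp[[xcol, ycol]].to_numpy(dtype=float) * scale
        if kind == "main":
            main.append(coords)
        elif kind == "branch":
            branches.append(coords)
        elif kind == "branch_point":
            points.extend(coords)
        else:
            raise ParseError(f"{path}: trace {tid!r} has unknown kind {kind!r}")
    ann = NerveAnnotation(
        image_id=meta.image_id if meta is not None else path.stem,
        main_fibers=main,
        branches=branches,
        branch_points=np.asarray(points, dtype=float).reshape(-1, 2),
    )
    fov = meta.fov_um if meta is not None else 400.0
    return ann.validate_bounds(fov)


def write_annotation(ann: NerveAnnotation, meta: ImageMeta, path) -> None:
    """Write the native JSON schema (µm coordinates, exact float round-trip)."""
    obj = {
        "image_id": ann.image_id,
        "units": "um",
        "meta": {
            "width_px": meta.width_px,
            "height_px": meta.height_px,
            "fov_um": meta.fov_um,
            "subject_id": meta.subject_id,
            "eye": meta.eye,
            "acquisition_index": meta.acquisition_index,
        },
        "main_fibers": [p.tolist() for p in ann.main_fibers],
        "branches": [p.tolist() for p in ann.branches],
        "branch_points": ann.branch_points.tolist(),
    }
    Path(path).write_text(json.dumps(obj))


# ---------------------------------------------------------------------------
# Focus-region I/O
# ---------------------------------------------------------------------------


def read_focus_region(path) -> FocusRegion:
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    if "image_id" not in obj or "center" not in obj:
        raise ParseError(f"{path}: focus region needs 'image_id' and 'center'")
    boundary = np.asarray(obj["polygon"], dtype=float) if "polygon" in obj else None
    angles = lengths = None
    if "rays" in obj:
        rays = obj["rays"]
        try:
            angles = np.array([r["angle"] for r in rays], dtype=float)
            lengths = np.array([r["l"] for r in rays], dtype=float)
        except (KeyError, TypeError) as exc:
            raise ParseError(f"{path}: each ray needs 'angle' and 'l'") from exc
    return FocusRegion(
        image_id=str(obj["image_id"]),
        center=np.asarray(obj["center"], dtype=float),
        boundary=boundary,
        ray_angles=angles,
        ray_lengths=lengths,
        a_after=float(obj["a_after"]) if "a_after" in obj else None,
    )


def write_focus_region(region: FocusRegion, path) -> None:
    obj: dict = {"image_id": region.image_id, "center": region.center.tolist()}
    if region.boundary is not None:
        obj["polygon"] = region.boundary.tolist()
    if region.ray_angles is not None:
        obj["rays"] = [
            {"angle": float(a), "l": float(l)}
            for a, l in zip(region.ray_angles, region.ray_lengths)
        ]
    if region.a_after is not None:
        obj["a_after"] = float(region.a_after)
    Path(path).write_text(json.dumps(obj))


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = ["subject_id", "group", "ienfd"] + [
    f"{m}_{mode}" for mode in MODES for m in METRIC_NAMES
] + [f"area_mm2_{mode}" for mode in MODES]


def write_results(records: Sequence[SubjectRecord], path) -> None:
    """Write one row per subject with both modes' CNFL/CNFD/CNBD, group and IENFD."""
    if not records:
        raise ValidationError("refusing to write an empty result table")
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group,
               "ienfd": np.nan if r.ienfd is None else r.ienfd}
        for mode in MODES:
            m = r.metrics(mode)
            row[f"cnfl_{mode}"] = m.cnfl
            row[f"cnfd_{mode}"] = m.cnfd
            row[f"cnbd_{mode}"] = m.cnbd
            row[f"area_mm2_{mode}"] = m.reference_area_mm2
        rows.append(row)
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(path, index=False)


def read_results(path) -> list:
    df = pd.read_csv(path)
    missing = set(_RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: result table missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        metrics = {}
        for mode in MODES:
            metrics[mode] = CCMMetrics(
                cnfl=float(row[f"cnfl_{mode}"]),
                cnfd=float(row[f"cnfd_{mode}"]),
                cnbd=float(row[f"cnbd_{mode}"]),
                reference_area_mm2=float(row[f"area_mm2_{mode}"]),
                mode=mode,
            )
        ienfd = row["ienfd"]
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                metrics_adjusted=metrics["adjusted"],
                metrics_unadjusted=metrics["unadjusted"],
                ienfd=None if pd.isna(ienfd) else float(ienfd),
            )
        )
    return records
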