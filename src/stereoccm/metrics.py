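"""Corneal nerve metrics: CNFL, CNFD, CNBD in unadjusted and adjusted modes.

Definitions (per reference area):

* CNFL — total length of main fibers *and* branches, mm/mm²;
* CNFD — number of main fibers, no./mm²;
* CNBD — number of primary branch points, no./mm².

The *unadjusted* (standard) mode uses the full annotation over the full frame
area (0.16 mm² at the default 400 × 400 µm frame).  The *adjusted* mode clips
the annotation to the star-shaped in-focus region and divides by the
nucleator-estimated in-focus area ``a_after``.

Clipping rules: polylines are intersected with the region polygon and may
split into several retained pieces; a main fiber counts once toward CNFD no
matter how many pieces survive; branch points on the boundary count as inside
(closed region).  CNBD uses the annotated branch points, not clipped branch
polyline counts.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, MultiLineString, Point, Polygon
from shapely.geometry import box as shapely_box

from .data_model import (
    CCMMetrics,
    FocusRegion,
    ImageMeta,
    NerveAnnotation,
    SubjectRecord,
    ValidationError,
)
from .focus_area import region_polygon

__all__ = [
    "clip_to_region",
    "compute_metrics",
    "adjusted_and_unadjusted",
    "aggregate_subject",
]

_ON_BOUNDARY_TOL = 1e-9


def _line_pieces(geom) -> list:
    """Retained polyline pieces (≥2 vertices, positive length) of a clip result."""
    pieces = []
    if geom.is_empty:
        return pieces
    if isinstance(geom, LineString):
        candidates = [geom]
    elif isinstance(geom, MultiLineString):
        candidates = list(geom.geoms)
    else:  # GeometryCollection: keep line parts, drop touch points
        candidates = [g for g in getattr(geom, "geoms", []) if isinstance(g, LineString)]
    for g in candidates:
        if g.length > 0 and len(g.coords) >= 2:
            pieces.append(np.asarray(g.coords, dtype=float))
    return pieces


def clip_to_region(
    annotation: NerveAnnotation,
    region: FocusRegion,
    fov_um: float | None = None,
) -> NerveAnnotation:
    """Intersect an annotation with the focus region.

    Returns a new annotation whose ``main_fiber_ids`` map retained pieces back
    to the original fibers, so CNFD still counts each split fiber once.  When
    the region covers the whole frame (and ``fov_um`` is given) the input is
    returned unchanged apart from identity bookkeeping.
    """
    poly = region_polygon(region)
    if not poly.is_valid:
        raise ValidationError(f"{region.image_id!r}: invalid region polygon")
    if fov_um is not None and poly.covers(shapely_box(0.0, 0.0, fov_um, fov_um)):
        return NerveAnnotation(
            image_id=annotation.image_id,
            main_fibers=[p.copy() for p in annotation.main_fibers],
            branches=[p.copy() for p in annotation.branches],
            branch_points=annotation.branch_points.copy(),
            main_fiber_ids=(
                list(annotation.main_fiber_ids)
                if annotation.main_fiber_ids is not None
                else list(range(len(annotation.main_fibers)))
            ),
        )

    main_pieces: list = []
    ids: list = []
    source_ids = (
        annotation.main_fiber_ids
        if annotation.main_fiber_ids is not None
        else list(range(len(annotation.main_fibers)))
    )
    for fid, polyline in zip(source_ids, annotation.main_fibers):
        for piece in _line_pieces(LineString(polyline).intersection(poly)):
            main_pieces.append(piece)
            ids.append(fid)
    branch_pieces: list = []
    for polyline in annotation.branches:
        branch_pieces.extend(_line_pieces(LineString(polyline).intersection(poly)))
    kept_points = [
        pt
        for pt in annotation.branch_points
        if poly.covers(Point(pt)) or poly.distance(Point(pt)) <= _ON_BOUNDARY_TOL
    ]
    return NerveAnnotation(
        image_id=annotation.image_id,
        main_fibers=main_pieces,
        branches=branch_pieces,
        branch_points=np.asarray(kept_points, dtype=float).reshape(-1, 2),
        main_fiber_ids=ids,
    )


def compute_metrics(
    annotation: NerveAnnotation, reference_area_mm2: float, mode: str
) -> CCMMetrics:
    """CNFL/CNFD/CNBD of one annotation over a reference area in mm²."""
    if reference_area_mm2 <= 0:
        raise ValidationError("reference_area_mm2 must be > 0")
    total_length_mm = annotation.total_length_um / 1000.0
    return CCMMetrics(
        cnfl=total_length_mm / reference_area_mm2,
        cnfd=annotation.n_main_fibers / reference_area_mm2,
        cnbd=annotation.n_branch_points / reference_area_mm2,
        reference_area_mm2=reference_area_mm2,
        mode=mode,
    )


def adjusted_and_unadjusted(
    annotation: NerveAnnotation,
    region: FocusRegion,
    meta: ImageMeta,
) -> tuple:
    """(adjusted, unadjusted) metrics for one image.

    Unadjusted: the full annotation over the frame area.  Adjusted: the
    annotation clipped to the region over ``a_after``.  When the region is the
    full frame with ``a_after = fov²`` the two are identical.
    """
    if region.a_after is None:
        raise ValidationError(
            f"{region.image_id!r}: region has no a_after; run nucleator_area first"
        )
    unadjusted = compute_metrics(annotation, meta.frame_area_mm2, "unadjusted")
    clipped = clip_to_region(annotation, region, fov_um=meta.fov_um)
    adjusted = compute_metrics(clipped, region.a_after / 1e6, "adjusted")
    return adjusted, unadjusted


def aggregate_subject(
    per_image: Sequence[tuple],
    subject_id: str,
    group: str,
    ienfd: float | None = None,
) -> SubjectRecord:
    """Arithmetic mean of per-image (adjusted, unadjusted) metric pairs."""
    if not per_image:
        raise ValidationError(f"subject {subject_id!r}: no images to aggregate")
    means = {}
    for mode, idx in (("adjusted", 0), ("unadjusted", 1)):
        ms = [pair[idx] for pair in per_image]
        if any(m.mode != mode for m in ms):
            raise ValidationError("per_image pairs must be (adjusted, unadjusted)")
        means[mode] = CCMMetrics(
            cnfl=float(np.mean([m.cnfl for m in ms])),
            cnfd=float(np.mean([m.cnfd for m in ms])),
            cnbd=float(np.mean([m.cnbd for m in ms])),
            reference_area_mm2=float(np.mean([m.reference_area_mm2 for m in ms])),
            mode=mode,
        )
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        metrics_adjusted=means["adjusted"],
        metrics_unadjusted=means["unadjusted"],
        ienfd=ienfd,
    )
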