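"""Orientation-stratified systematic uniform random (SUR) image sampling.

CCM scans yield on the order of a hundred images per session, from which a
small fixed number is analysed.  Subjective selection ("best focus, best
contrast") invites bias; the sampling scheme here removes it in two steps:

1. every image is assigned to an orientation stratum — *vertical*,
   *diagonal left* or *diagonal right* — from the length-weighted dominant
   direction of its traced main fibers (an axial quantity, so averaging uses
   doubled angles), which proxies for position on the cornea;
2. within each stratum a fixed number of images is drawn by systematic
   sampling with a real-valued interval: interval ``T = n/k``, random start
   ``u ~ U[0, T)``, picks at ``floor(u + i·T)``.  Every image has inclusion
   probability exactly ``k/n`` and exactly ``k`` images are returned.

The default plan selects 8 images per subject: 4 vertical, 2 diagonal-left,
2 diagonal-right.

Orientation bins partition the axial range [0°, 180°) into three 60°
sectors: vertical = 90° ± 30°, diagonal-right = [0°, 60°), diagonal-left =
(120°, 180°).  Angles follow the image coordinate convention (x rightward,
y downward), so "vertical" means predominantly top-to-bottom fibers.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import (
    ORIENTATIONS,
    ImageMeta,
    NerveAnnotation,
    ValidationError,
)

__all__ = [
    "SamplingPlan",
    "PoolImage",
    "ImagePool",
    "SelectedImage",
    "classify_orientation",
    "dominant_axial_angle_deg",
    "systematic_sample",
    "select_images",
    "build_pool",
]

logger = logging.getLogger(__name__)

DEFAULT_STRATA = (("vertical", 4), ("diagonal_left", 2), ("diagonal_right", 2))

#: half-width (degrees) of the vertical sector about 90°
VERTICAL_HALF_WIDTH_DEG = 30.0


@dataclass(frozen=True)
class SamplingPlan:
    """Ordered strata with fixed per-stratum sample sizes and a root seed."""

    strata: tuple = DEFAULT_STRATA
    seed: int = 0

    def __post_init__(self) -> None:
        for name, k in self.strata:
            if name not in ORIENTATIONS:
                raise ValidationError(f"unknown stratum {name!r}")
            if k < 0:
                raise ValidationError(f"n_select for {name!r} must be ≥ 0")

    @property
    def total(self) -> int:
        return sum(k for _, k in self.strata)


@dataclass(frozen=True)
class PoolImage:
    meta: ImageMeta
    annotation: NerveAnnotation
    orientation: str


@dataclass(frozen=True)
class SelectedImage:
    meta: ImageMeta
    annotation: NerveAnnotation
    stratum: str


@dataclass
class ImagePool:
    """All classifiable images of one subject, ordered by acquisition index."""

    subject_id: str
    images: list = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [im.meta.acquisition_index for im in self.images]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"{self.subject_id!r}: acquisition indices must be strictly increasing"
            )

    def stratum(self, orientation: str) -> list:
        return [im for im in self.images if im.orientation == orientation]


def dominant_axial_angle_deg(annotation: NerveAnnotation) -> float:
    """Length-weighted dominant fiber orientation in degrees, in [0, 180).

    Fiber direction is axial (a fiber traced tip-to-base or base-to-tip is the
    same fiber), so segment angles are averaged on the doubled circle:
    ``θ̄ = ½·arg Σ w·e^{2iθ}`` with segment lengths as weights.
    """
    if not annotation.main_fibers:
        raise ValidationError(
            f"unclassifiable image {annotation.image_id!r}: no main fibers"
        )
    z = 0.0 + 0.0j
    for poly in annotation.main_fibers:
        d = np.diff(poly, axis=0)
        w = np.linalg.norm(d, axis=1)
        theta = np.arctan2(d[:, 1], d[:, 0])
        z += complex(np.sum(w * np.cos(2 * theta)), np.sum(w * np.sin(2 * theta)))
    angle = 0.5 * math.atan2(z.imag, z.real)
    return math.degrees(angle) % 180.0


def classify_orientation(annotation: NerveAnnotation) -> str:
    """Assign an image to ``vertical``, ``diagonal_left`` or ``diagonal_right``.

    ``vertical`` if the dominant axial angle is within 30° of 90°;
    ``diagonal_right`` for [0°, 60°); ``diagonal_left`` for (120°, 180°).
    """
    theta = dominant_axial_angle_deg(annotation)
    if abs(theta - 90.0) <= VERTICAL_HALF_WIDTH_DEG:
        return "vertical"
    if theta < 90.0:
        return "diagonal_right"
    return "diagonal_left"


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def systematic_sample(items: Sequence, k: int, seed) -> list:
    """Systematic uniform random sample of exactly ``k`` of ``len(items)`` items.

    Uses a real-valued sampling interval ``T = n/k`` and a random start
    ``u ~ U[0, T)``; item indices are ``floor(u + i·T)``, ``i = 0..k−1``.
    Order is preserved, there are no duplicates, and every item has inclusion
    probability exactly ``k/n``.

    ``seed`` may be an integer, a ``numpy.random.Generator``, or any object
    with a ``uniform(low, high)`` method (useful for deterministic tests).
    """
    n = len(items)
    if k < 0:
        raise ValidationError("k must be ≥ 0")
    if k > n:
        raise ValidationError(f"cannot select {k} items from {n}")
    if k == 0:
        return []
    rng = seed if hasattr(seed, "uniform") else _as_rng(seed)
    T = n / k
    u = float(rng.uniform(0.0, T))
    idx = np.floor(u + T * np.arange(k)).astype(int)
    idx = np.clip(idx, 0, n - 1)  # guards u == T from a pathological generator
    assert len(np.unique(idx)) == k, "systematic indices must be distinct"
    return [items[i] for i in idx]


def _child_rng(root_seed: int, subject_id: str, stratum_index: int) -> np.random.Generator:
    # Hash the subject id so adding or removing a subject never perturbs the
    # selections of the others.
    subject_key = zlib.crc32(subject_id.encode("utf-8"))
    ss = np.random.SeedSequence(root_seed, spawn_key=(subject_key, stratum_index))
    return np.random.default_rng(ss)


def build_pool(subject_id: str, images: Sequence[tuple]) -> ImagePool:
    """Classify (meta, annotation) pairs into strata and assemble a pool.

    Images whose annotation has no main fibers cannot be assigned an
    orientation; they are dropped with a warning rather than failing the
    subject.
    """
    ordered = sorted(images, key=lambda pair: pair[0].acquisition_index)
    pool_images = []
    for meta, ann in ordered:
        try:
            orient = classify_orientation(ann)
        except ValidationError:
            logger.warning(
                "subject %s: image %s has no main fibers; excluded from the pool",
                subject_id, meta.image_id,
            )
            continue
        pool_images.append(PoolImage(meta=meta, annotation=ann, orientation=orient))
    return ImagePool(subject_id=subject_id, images=pool_images)


def select_images(pool: ImagePool, plan: SamplingPlan | None = None) -> list:
    """Systematic-random selection per stratum with the plan's fixed sizes.

    Under-populated strata contribute all their images (with a warning); the
    selection size is therefore ``Σ min(n_select, stratum size)``.
    """
    if plan is None:
        plan = SamplingPlan()
    if not pool.images:
        raise ValidationError(f"subject {pool.subject_id!r}: empty image pool")
    selected = []
    for stratum_index, (orientation, n_select) in enumerate(plan.strata):
        items = pool.stratum(orientation)
        k = n_select
        if len(items) < n_select:
            logger.warning(
                "subject %s: stratum %s has %d image(s), fewer than the planned %d; taking all",
                pool.subject_id, orientation, len(items), n_select,
            )
            k = len(items)
        rng = _child_rng(plan.seed, pool.subject_id, stratum_index)
        for im in systematic_sample(items, k, rng):
            selected.append(
                SelectedImage(meta=im.meta, annotation=im.annotation, stratum=orientation)
            )
    return selected
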