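import math

import numpy as np
import pytest

from stereoccm.data_model import FocusRegion, ImageMeta, NerveAnnotation, ValidationError
from stereoccm.focus_area import full_frame_region, nucleator_area, region_polygon
from stereoccm.metrics import (
    adjusted_and_unadjusted,
    aggregate_subject,
    clip_to_region,
    compute_metrics,
)
from stereoccm.synthetic import SynthParams, generate_image


def _disk_region(radius=100.0, n=64):
    angles = np.linspace(0, 2 * math.pi, n, endpoint=False)
    pts = np.stack([200 + radius * np.cos(angles), 200 + radius * np.sin(angles)], axis=1)
    return FocusRegion(image_id="img", center=np.array([200.0, 200.0]), boundary=pts)


# -- clipping -----------------------------------------------------------------


def test_full_frame_clip_is_identity(meta, simple_annotation):
    region = full_frame_region(meta)
    clipped = clip_to_region(simple_annotation, region, fov_um=meta.fov_um)
    assert clipped == simple_annotation


def test_central_chord_length(meta, simple_annotation):
    """A horizontal diameter of a centered 100-µm disk retains 200 µm."""
    clipped = clip_to_region(simple_annotation, _disk_region(100.0), fov_um=meta.fov_um)
    assert clipped.main_length_um == pytest.approx(200.0, rel=1e-9)
    assert clipped.n_main_fibers == 1


def test_length_conservation_random_pairs(meta, rng):
    from shapely.geometry import LineString

    for _ in range(200):
        n_pts = rng.integers(2, 6)
        fiber = rng.uniform(0, 400, (n_pts, 2))
        radius = rng.uniform(40, 180)
        region = _disk_region(radius)
        poly = region_polygon(region)
        line = LineString(fiber)
        inside = line.intersection(poly).length
        outside = line.difference(poly).length
        assert inside + outside == pytest.approx(line.length, rel=1e-6)
        clipped = clip_to_region(
            NerveAnnotation(image_id="img", main_fibers=[fiber]), region, meta.fov_um
        )
        assert clipped.main_length_um == pytest.approx(inside, rel=1e-9, abs=1e-9)


def test_clipping_idempotent(meta, rng):
    region = _disk_region(120.0)
    ann = NerveAnnotation(
        image_id="img",
        main_fibers=[rng.uniform(0, 400, (4, 2)) for _ in range(5)],
        branch_points=rng.uniform(0, 400, (6, 2)),
    )
    once = clip_to_region(ann, region, meta.fov_um)
    twice = clip_to_region(once, region, meta.fov_um)
    assert twice.main_length_um == pytest.approx(once.main_length_um, rel=1e-9)
    assert twice.n_main_fibers == once.n_main_fibers
    assert twice.n_branch_points == once.n_branch_points


def test_split_fiber_counts_once(meta):
    """A fiber crossing the region twice keeps two pieces but one identity."""
    zigzag = np.array(
        [[0.0, 200.0], [150.0, 200.0], [200.0, 390.0], [250.0, 200.0], [400.0, 200.0]]
    )
    ann = NerveAnnotation(image_id="img", main_fibers=[zigzag])
    clipped = clip_to_region(ann, _disk_region(100.0), fov_um=meta.fov_um)
    assert len(clipped.main_fibers) >= 2
    assert clipped.n_main_fibers == 1


def test_branch_point_on_boundary_counts_inside(meta):
    region = _disk_region(100.0)
    boundary_pt = region.boundary[0]  # exactly on the polygon
    ann = NerveAnnotation(image_id="img", branch_points=[boundary_pt, [10.0, 10.0]])
    clipped = clip_to_region(ann, region, meta.fov_um)
    assert clipped.n_branch_points == 1  # boundary point kept, far corner dropped


# -- metric computation -------------------------------------------------------


def test_empty_annotation_gives_zeros():
    m = compute_metrics(NerveAnnotation(image_id="img"), 0.16, "unadjusted")
    assert m.as_tuple() == (0.0, 0.0, 0.0)


def test_single_fiber_hand_arithmetic(simple_annotation):
    """400 µm of fiber over 0.16 mm²: CNFL 2.5 mm/mm², CNFD 6.25 /mm²."""
    m = compute_metrics(simple_annotation, 0.16, "unadjusted")
    assert m.cnfl == pytest.approx(2.5)
    assert m.cnfd == pytest.approx(6.25)
    assert m.cnbd == 0.0


def test_halving_area_doubles_densities(simple_annotation):
    full = compute_metrics(simple_annotation, 0.16, "unadjusted")
    half = compute_metrics(simple_annotation, 0.08, "adjusted")
    assert half.cnfl == pytest.approx(2 * full.cnfl)
    assert half.cnfd == pytest.approx(2 * full.cnfd)


def test_nonpositive_area_rejected(simple_annotation):
    with pytest.raises(ValidationError):
        compute_metrics(simple_annotation, 0.0, "unadjusted")


def test_unit_coherence_under_scaling(rng):
    """Scaling coordinates by s and area by s² scales CNFL by 1/s, counts by 1/s²."""
    ann = NerveAnnotation(
        image_id="img",
        main_fibers=[rng.uniform(0, 400, (4, 2)) for _ in range(3)],
        branch_points=rng.uniform(0, 400, (5, 2)),
    )
    s = 2.5
    base = compute_metrics(ann, 0.16, "unadjusted")
    scaled = compute_metrics(ann.scaled(s), 0.16 * s * s, "unadjusted")
    assert scaled.cnfl == pytest.approx(base.cnfl / s, rel=1e-12)
    assert scaled.cnfd == pytest.approx(base.cnfd / (s * s), rel=1e-12)
    assert scaled.cnbd == pytest.approx(base.cnbd / (s * s), rel=1e-12)


def test_revertexing_invariance(simple_annotation):
    """Densifying polyline vertices changes no metric."""
    poly = simple_annotation.main_fibers[0]
    t = np.linspace(0, 1, 57)[:, None]
    dense = poly[0] + t * (poly[1] - poly[0])
    dense_ann = NerveAnnotation(image_id="img", main_fibers=[dense])
    a = compute_metrics(simple_annotation, 0.16, "unadjusted")
    b = compute_metrics(dense_ann, 0.16, "unadjusted")
    assert b.cnfl == pytest.approx(a.cnfl, rel=1e-9)
    assert b.cnfd == a.cnfd


# -- adjusted vs unadjusted ---------------------------------------------------


def test_full_frame_region_gives_identical_modes(meta, simple_annotation):
    region = full_frame_region(meta)
    adj, unadj = adjusted_and_unadjusted(simple_annotation, region, meta)
    assert adj.as_tuple() == unadj.as_tuple()
    assert adj.reference_area_mm2 == unadj.reference_area_mm2


def test_structures_inside_smaller_region_increase_densities(meta):
    """Everything in focus, smaller reference area ⇒ adjusted ≥ unadjusted."""
    ann = NerveAnnotation(
        image_id="img",
        main_fibers=[np.array([[150.0, 200.0], [250.0, 200.0]])],
        branch_points=np.array([[200.0, 210.0]]),
    )
    region = nucleator_area(_disk_region(100.0), n_rays=4, seed=0, meta=meta)
    adj, unadj = adjusted_and_unadjusted(ann, region, meta)
    assert adj.cnfl >= unadj.cnfl
    assert adj.cnfd >= unadj.cnfd
    assert adj.cnbd >= unadj.cnbd


def test_adjusted_recovers_known_density_unadjusted_underestimates():
    """With out-of-focus fibers invisible, only the adjusted mode recovers the
    true in-focus intensity."""
    params = SynthParams(branch_rate=0.0)
    rng = np.random.default_rng(9)
    adj_vals, unadj_vals = [], []
    for i in range(120):
        im = generate_image(params, rng, "vertical", image_id=f"i{i}")
        region = nucleator_area(im.region, n_rays=4, seed=rng, meta=im.meta)
        adj, unadj = adjusted_and_unadjusted(im.visible, region, im.meta)
        adj_vals.append(adj.cnfl)
        unadj_vals.append(unadj.cnfl)
    lam = params.fiber_intensity
    assert np.mean(adj_vals) == pytest.approx(lam, rel=0.05)
    assert np.mean(unadj_vals) < 0.9 * lam


# -- aggregation --------------------------------------------------------------


def _pair(cnfl):
    from stereoccm.data_model import CCMMetrics

    return (
        CCMMetrics(cnfl, 10.0, 20.0, 0.1, "adjusted"),
        CCMMetrics(cnfl / 2, 5.0, 10.0, 0.16, "unadjusted"),
    )


def test_single_image_aggregate_is_identity():
    rec = aggregate_subject([_pair(10.0)], "s1", "control", ienfd=5.0)
    assert rec.metrics_adjusted.cnfl == 10.0
    assert rec.metrics_unadjusted.cnfl == 5.0
    assert rec.ienfd == 5.0


def test_mean_of_two_images():
    rec = aggregate_subject([_pair(10.0), _pair(20.0)], "s1", "control")
    assert rec.metrics_adjusted.cnfl == pytest.approx(15.0)


def test_aggregate_idempotent_on_identical_images():
    rec1 = aggregate_subject([_pair(7.0)] * 5, "s1", "dspn_minus")
    rec2 = aggregate_subject([_pair(7.0)], "s1", "dspn_minus")
    assert rec1.metrics_adjusted.cnfl == rec2.metrics_adjusted.cnfl


def test_aggregate_empty_is_error():
    with pytest.raises(ValidationError):
        aggregate_subject([], "s1", "control")
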