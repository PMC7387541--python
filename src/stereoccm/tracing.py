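"""Automated nerve tracing from grayscale images — a documented stand-in.

This tracer exists to close the loop on synthetic images (image → annotation
→ metrics); it makes no claim of equivalence with clinical tracing software,
and the stereological core is always validated against ground-truth
annotations, never traced ones.

Pipeline: multiscale tubularity (Sato ridge filter) → Otsu threshold →
skeletonization → skeleton graph (endpoints / junctions / degree-2 chains) →
per connected component, the longest path is the main fiber, remaining chains
hanging off it are branches, and junction nodes on the main path are branch
points.  Components whose main path is shorter than ``min_length_um`` are
discarded as noise.  Coordinates convert to µm with the pixel-center rule
``(j + 0.5)·s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.ndimage as ndi
from skimage.filters import sato, threshold_otsu
from skimage.morphology import skeletonize

from .data_model import ImageMeta, NerveAnnotation, ValidationError

__all__ = ["TraceParams", "trace_nerves", "match_annotations", "MatchReport"]

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class TraceParams:
    scales_px: tuple = (1.0, 2.0, 4.0)   # tubularity filter scales
    min_length_um: float = 50.0          # shortest accepted main fiber
    min_branch_um: float = 8.0           # shortest accepted branch
    min_object_px: int = 20              # pre-skeleton speckle removal
    min_contrast: float = 4.0            # required ridge response over noise


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """Graph with one node per skeleton pixel, 8-connected."""
    g = nx.Graph()
    coords = np.argwhere(skel)
    coord_set = set(map(tuple, coords))
    for y, x in coord_set:
        g.add_node((y, x))
    for y, x in coord_set:
        for dy, dx in _NEIGHBORS:
            nb = (y + dy, x + dx)
            if nb in coord_set and not g.has_edge((y, x), nb):
                g.add_edge((y, x), nb, weight=float(np.hypot(dy, dx)))
    return g


def _chain_graph(g: nx.Graph) -> nx.Graph:
    """Condense degree-2 pixel chains into weighted edges between nodes of
    degree ≠ 2; edge attribute ``path`` holds the pixel polyline."""
    nodes = [n for n in g.nodes if g.degree(n) != 2]
    cg = nx.MultiGraph()
    cg.add_nodes_from(nodes)
    visited_edges = set()
    for start in nodes:
        for nb in g.neighbors(start):
            key = frozenset({start, nb})
            if key in visited_edges and g.degree(nb) != 2:
                continue
            path = [start, nb]
            prev, cur = start, nb
            while g.degree(cur) == 2:
                nxt = next(n for n in g.neighbors(cur) if n != prev)
                path.append(nxt)
                prev, cur = cur, nxt
            edge_pixels = frozenset(path)
            if (path[-1], edge_pixels) in visited_edges or (path[0], edge_pixels) in visited_edges:
                continue
            visited_edges.add((path[0], edge_pixels))
            visited_edges.add((path[-1], edge_pixels))
            length = sum(
                float(np.hypot(a[0] - b[0], a[1] - b[1])) for a, b in zip(path, path[1:])
            )
            cg.add_edge(path[0], path[-1], weight=length, path=path)
    # isolated cycles (no degree≠2 node) are rare and ignored by this tracer
    return cg


def _longest_path(cg: nx.Graph, component_nodes) -> list:
    """Approximate longest simple path (double-sweep on a spanning tree)."""
    sub = cg.subgraph(component_nodes)
    simple = nx.Graph()
    for u, v, data in sub.edges(data=True):
        if simple.has_edge(u, v):
            if data["weight"] <= simple[u][v]["weight"]:
                continue
        simple.add_edge(u, v, **data)
    tree = nx.maximum_spanning_tree(simple, weight="weight")
    if tree.number_of_nodes() == 1:
        return []
    def farthest(source):
        dist = nx.single_source_dijkstra_path_length(tree, source, weight="weight")
        node = max(dist, key=dist.get)
        return node, dist[node]
    a, _ = farthest(next(iter(tree.nodes)))
    b, _ = farthest(a)
    return nx.shortest_path(tree, a, b, weight=lambda u, v, d: -0.0 + d["weight"])


def _path_polyline(cg: nx.Graph, node_path: list) -> list:
    """Concatenate the pixel chains along a node path."""
    pixels: list = []
    for u, v in zip(node_path, node_path[1:]):
        datas = (
            [d for _, _, d in cg.edges(nbunch=[u], data=True) if True]
            if False
            else None
        )
        best = None
        if cg.is_multigraph():
            for key, data in cg[u][v].items():
                if best is None or data["weight"] > best["weight"]:
                    best = data
        else:
            best = cg[u][v]
        chain = list(best["path"])
        if chain[0] != u:
            chain = chain[::-1]
        if pixels and pixels[-1] == chain[0]:
            chain = chain[1:]
        pixels.extend(chain)
    return pixels


def _px_to_um(pixels, meta: ImageMeta) -> np.ndarray:
    s = meta.um_per_px
    arr = np.asarray(pixels, dtype=float)
    # pixels are (row, col); µm coordinates are (x, y)
    out = np.stack([(arr[:, 1] + 0.5) * s, (arr[:, 0] + 0.5) * s], axis=1)
    return np.clip(out, 0.0, meta.fov_um)


def trace_nerves(
    image: np.ndarray, meta: ImageMeta, params: TraceParams | None = None
) -> NerveAnnotation:
    """Trace nerve fibers, branches and branch points from a grayscale image.

    Deterministic given image and parameters.  A blank (structure-free) image
    yields an empty annotation rather than an error.
    """
    if params is None:
        params = TraceParams()
    img = np.asarray(image, dtype=float)
    if img.shape != (meta.height_px, meta.width_px):
        raise ValidationError("image shape does not match meta dimensions")
    if np.ptp(img) == 0:
        return NerveAnnotation(image_id=meta.image_id)
    ridge = sato(img, sigmas=params.scales_px, black_ridges=False, mode="reflect")
    noise = 1.4826 * float(np.median(np.abs(ridge - np.median(ridge)))) + 1e-12
    try:
        thr = max(threshold_otsu(ridge), params.min_contrast * noise)
    except ValueError:
        return NerveAnnotation(image_id=meta.image_id)
    mask = ridge > thr
    labels, n_labels = ndi.label(mask, structure=np.ones((3, 3)))
    if n_labels:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = np.isin(labels, np.nonzero(sizes >= params.min_object_px)[0])
    if not mask.any():
        return NerveAnnotation(image_id=meta.image_id)
    skel = skeletonize(mask)
    g = _skeleton_graph(skel)
    cg = _chain_graph(g)
    s = meta.um_per_px
    main_fibers, branches, branch_points = [], [], []
    for comp in nx.connected_components(cg):
        if len(comp) < 2:
            continue
        node_path = _longest_path(cg, comp)
        if len(node_path) < 2:
            continue
        pixels = _path_polyline(cg, node_path)
        poly = _px_to_um(pixels, meta)
        length = float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())
        if length < params.min_length_um:
            continue
        main_fibers.append(poly)
        on_main = set(node_path)
        sub = cg.subgraph(comp)
        main_edges = set()
        for u, v in zip(node_path, node_path[1:]):
            main_edges.add(frozenset({u, v}))
        for u, v, data in sub.edges(data=True):
            if frozenset({u, v}) in main_edges:
                main_edges.discard(frozenset({u, v}))  # consume one parallel edge
                continue
            chain = _px_to_um(data["path"], meta)
            blen = float(np.linalg.norm(np.diff(chain, axis=0), axis=1).sum())
            if blen < params.min_branch_um:
                continue
            branches.append(chain)
            anchor = u if u in on_main else (v if v in on_main else None)
            if anchor is not None:
                branch_points.append(_px_to_um([anchor], meta)[0])
    # deduplicate branch points that coincide (several branches off one node)
    if branch_points:
        uniq: list = []
        for pt in branch_points:
            if not any(np.hypot(*(pt - q)) < 2 * s for q in uniq):
                uniq.append(pt)
        branch_points = uniq
    return NerveAnnotation(
        image_id=meta.image_id,
        main_fibers=main_fibers,
        branches=branches,
        branch_points=np.asarray(branch_points, dtype=float).reshape(-1, 2),
    )


# ---------------------------------------------------------------------------
# matching predicted annotations against ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchReport:
    fiber_recall: float
    fiber_precision: float
    branch_point_recall: float
    branch_point_precision: float
    cnfl_relative_error: float
    n_truth_fibers: int
    n_predicted_fibers: int


def _polyline_distance(a: np.ndarray, b: np.ndarray, step_um: float = 5.0) -> float:
    """Symmetric mean closest-point distance between two polylines."""
    from shapely.geometry import LineString

    la, lb = LineString(a), LineString(b)

    def one_way(src: LineString, dst: LineString) -> float:
        n = max(int(src.length / step_um), 2)
        ds = [dst.distance(src.interpolate(t, normalized=True)) for t in np.linspace(0, 1, n)]
        return float(np.mean(ds))

    return 0.5 * (one_way(la, lb) + one_way(lb, la))


def match_annotations(
    predicted: NerveAnnotation, truth: NerveAnnotation, tolerance_um: float = 5.0
) -> MatchReport:
    """Greedy one-to-one fiber and branch-point matching within a tolerance."""
    pred_fibers = list(predicted.main_fibers)
    true_fibers = list(truth.main_fibers)
    pairs = []
    for i, tf in enumerate(true_fibers):
        for j, pf in enumerate(pred_fibers):
            d = _polyline_distance(tf, pf)
            if d <= tolerance_um:
                pairs.append((d, i, j))
    pairs.sort()
    used_t, used_p = set(), set()
    matches = 0
    for d, i, j in pairs:
        if i in used_t or j in used_p:
            continue
        used_t.add(i)
        used_p.add(j)
        matches += 1
    fiber_recall = matches / len(true_fibers) if true_fibers else 1.0
    fiber_precision = matches / len(pred_fibers) if pred_fibers else 1.0

    tp_pts = 0
    used = set()
    for tp in truth.branch_points:
        best, best_j = np.inf, None
        for j, pp in enumerate(predicted.branch_points):
            if j in used:
                continue
            d = float(np.hypot(*(tp - pp)))
            if d < best:
                best, best_j = d, j
        if best_j is not None and best <= tolerance_um:
            used.add(best_j)
            tp_pts += 1
    n_true_pts = truth.n_branch_points
    n_pred_pts = predicted.n_branch_points
    pt_recall = tp_pts / n_true_pts if n_true_pts else 1.0
    pt_precision = tp_pts / n_pred_pts if n_pred_pts else 1.0

    true_len = truth.total_length_um
    pred_len = predicted.total_length_um
    cnfl_err = 0.0 if true_len == 0 else (pred_len - true_len) / true_len
    return MatchReport(
        fiber_recall=fiber_recall,
        fiber_precision=fiber_precision,
        branch_point_recall=pt_recall,
        branch_point_precision=pt_precision,
        cnfl_relative_error=float(cnfl_err),
        n_truth_fibers=len(true_fibers),
        n_predicted_fibers=len(pred_fibers),
    )
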